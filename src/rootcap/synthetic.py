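"""Seeded generators for pot, field, soil and harvest datasets.

Every downstream stage is testable against these generators, which emulate
the statistical structure of the real measurements:

* pot wetting-up series with exponential C_R–theta_rel dependence,
  multiplicative lognormal measurement noise, and a saturated tenth
  reading that defines each plant's own normaliser (as in the protocol:
  the noisy saturated reading IS the plant's C_R*);
* a linear root-dry-mass to saturated-capacitance relation;
* field campaigns with per-day theta_rel means/CVs and a unimodal
  seasonal C_R* profile peaking at flowering, with a small multiplicative
  inoculation uplift inside a mid-season window;
* soil capacitance following a power law in theta_rel, at least an order
  of magnitude above root capacitance;
* harvest shoot dry mass growing along a logistic curve, with AMF
  colonization intensity rising steeply during pod filling.

Per-day theta_rel statistics and the seasonal C_R* template are lookup
tables keyed to the published field campaigns (one row per measurement
day), not parametric curves.  All generators are bit-deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CapacitanceReading,
    FieldCampaign,
    HarvestRecord,
    PlantCalibrationSeries,
    Species,
    Treatment,
)
from .normalization import PRINTED_CONSTANTS, apparent_capacitance, species_calibration

# ---------------------------------------------------------------------------
# Published field campaign tables: per measurement day, mean and SD of
# theta_rel and of raw C_R (nF), plus the BBCH phenology code.

#: maize campaign, 10 days, n = 48 plants/day (3 row-segments x 16)
MAIZE_FIELD_TABLE = [
    # (das, theta_mean, theta_sd, cr_mean, cr_sd, bbch)
    (36, 0.516, 0.054, 4.71, 0.86, 14),
    (50, 0.488, 0.045, 15.09, 2.78, 17),
    (64, 0.236, 0.023, 13.74, 2.60, 19),
    (78, 0.537, 0.067, 34.46, 3.84, 63),
    (92, 0.338, 0.033, 25.02, 3.63, 67),
    (106, 0.214, 0.018, 16.24, 1.73, 73),
    (123, 0.547, 0.052, 19.28, 2.76, 83),
    (134, 0.237, 0.023, 7.06, 0.78, 87),
    (147, 0.266, 0.023, 5.24, 1.37, 89),
    (161, 0.521, 0.041, 2.35, 0.41, 97),
]

#: soybean control plots
SOYBEAN_CON_TABLE = [
    (39, 0.413, 0.033, 2.00, 0.12, 12),
    (54, 0.245, 0.018, 2.47, 0.26, 14),
    (69, 0.401, 0.036, 5.21, 0.46, 60),
    (83, 0.354, 0.038, 8.77, 0.69, 65),
    (97, 0.319, 0.025, 8.25, 0.64, 73),
    (113, 0.632, 0.037, 12.36, 1.05, 75),
    (125, 0.278, 0.021, 6.93, 0.53, 77),
    (139, 0.326, 0.028, 4.81, 0.58, 81),
    (150, 0.655, 0.038, 3.55, 0.30, 85),
    (162, 0.743, 0.031, 2.14, 0.26, 89),
]

#: soybean inoculated plots
SOYBEAN_INO_TABLE = [
    (39, 0.415, 0.031, 2.01, 0.13, 12),
    (54, 0.242, 0.019, 2.58, 0.27, 14),
    (69, 0.400, 0.032, 5.35, 0.42, 60),
    (83, 0.356, 0.033, 8.98, 0.70, 65),
    (97, 0.325, 0.022, 8.41, 0.63, 73),
    (113, 0.641, 0.034, 12.70, 1.28, 75),
    (125, 0.276, 0.024, 6.99, 0.55, 77),
    (139, 0.330, 0.024, 4.86, 0.56, 81),
    (150, 0.663, 0.031, 3.61, 0.29, 85),
    (162, 0.746, 0.029, 2.19, 0.27, 89),
]

FIELD_TABLES = {
    (Species.MAIZE, Treatment.NONE): MAIZE_FIELD_TABLE,
    (Species.SOYBEAN, Treatment.CON): SOYBEAN_CON_TABLE,
    (Species.SOYBEAN, Treatment.INO): SOYBEAN_INO_TABLE,
}

#: observed root-dry-mass ranges (g) at harvest of the pot experiment
RDM_RANGES = {Species.MAIZE: (0.37, 11.10), Species.SOYBEAN: (0.32, 6.21)}

#: nF of saturated capacitance per gram root dry mass; chosen so the
#: largest pot plants reach the observed maxima (42.1 nF at 11.1 g maize,
#: 12.7 nF at 6.2 g soybean)
MASS_SLOPES = {Species.MAIZE: 3.8, Species.SOYBEAN: 2.05}


@dataclass
class FieldDay:
    das: int
    mean_theta: float
    theta_cv: float
    mean_cstar: float  # nF, the day's true mean apparent capacitance
    bbch: Optional[int] = None


def default_field_days(
    species: Species | str, treatment: Treatment | str = Treatment.CON
) -> list[FieldDay]:
    """Seasonal template from the published campaign tables.

    The per-day true mean C_R* is obtained by applying the printed
    inversion constants to the day's mean C_R and mean theta_rel (the
    Jensen gap at these dispersions is < 2%, so this is a faithful
    template).
    """
    species = Species(species)
    treatment = Treatment(treatment)
    if species is Species.MAIZE:
        treatment = Treatment.NONE
    cal = species_calibration(species, "printed")
    days = []
    for das, tm, tsd, crm, _, bbch in FIELD_TABLES[(species, treatment)]:
        days.append(
            FieldDay(
                das=das,
                mean_theta=tm,
                theta_cv=tsd / tm,
                mean_cstar=apparent_capacitance(crm, tm, cal),
                bbch=bbch,
            )
        )
    return days


@dataclass
class SimConfig:
    """Full parameterization of the synthetic generators.

    Defaults reproduce the study conditions: 15 pot plants per species on
    a 10-level theta_rel grid from near wilting point (0.204) to
    saturation; generating calibration constants equal to the published
    species fits; multiplicative lognormal measurement noise sigma_ln =
    0.10 on ln C_R; field days with n = 48 plants across 3 replicate
    groups; a ~5% inoculation uplift of apparent capacitance between DAS
    40 and 90 (the size of the published 4-node-stage treatment effect);
    soil power law 350.3 * theta^1.086 with ln-noise 0.13 (sized to an
    ln-scale R² near 0.93).
    """

    seed: int = 0
    species: Species = Species.MAIZE
    # pot generator
    n_plants: int = 15
    theta_grid: tuple = ()
    gen_a: float = 0.0
    gen_b: float = 0.0
    sigma_ln: float = 0.10
    rdm_range: tuple = ()
    mass_slope: float = 0.0
    mass_intercept: float = 0.3
    mass_noise: float = 0.20
    age_range: tuple = (13, 62)
    # field generator
    field_days: tuple = ()
    n_per_day: int = 48
    n_groups: int = 3
    sigma_plant: float = 0.10
    treatment_uplift: float = 0.049
    uplift_window: tuple = (40, 90)
    # soil generator
    soil_coeff: float = 350.3
    soil_expnt: float = 1.086
    soil_sigma: float = 0.13
    soil_n: int = 300
    soil_theta_range: tuple = (0.2, 1.0)
    # harvest generator (soybean trial)
    harvest_days: tuple = (48, 71, 99, 135)
    plants_per_plot: int = 6
    final_day: int = 164
    final_per_plot: int = 10
    n_plots: int = 3
    sdm_final: float = 49.8
    sdm_cv: float = 0.30
    sdm_growth_rate: float = 0.06
    sdm_midpoint: float = 95.0
    sdm_uplift: float = 0.25
    grain_frac: float = 0.39
    m_low: float = 20.0
    m_high: float = 80.0
    m_rise_rate: float = 0.15
    m_midpoint: float = 117.0
    m_sd: float = 7.0
    m_uplift_pts: float = 5.0

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        printed = PRINTED_CONSTANTS[self.species]
        if not self.gen_a:
            self.gen_a = printed["a"]
        if not self.gen_b:
            self.gen_b = printed["b"]
        if not self.rdm_range:
            self.rdm_range = RDM_RANGES[self.species]
        if not self.mass_slope:
            self.mass_slope = MASS_SLOPES[self.species]
        if not self.theta_grid:
            # 10 wetting-up levels: wilting point (0.097/0.476) to saturation
            self.theta_grid = tuple(np.linspace(0.204, 1.0, 10))
        if not self.field_days:
            self.field_days = tuple(default_field_days(self.species))
        grid = np.asarray(self.theta_grid)
        if np.any(np.diff(grid) <= 0) or grid[-1] != 1.0:
            raise ValueError("theta_grid must be strictly increasing, ending at 1.0")
        if self.sigma_ln < 0 or self.sigma_plant < 0 or self.soil_sigma < 0:
            raise ValueError("noise SDs must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------

def _lognorm_factor(rng: np.random.Generator, sigma: float, size=None):
    """exp(N(0, sigma^2)) multiplicative noise; exactly 1 when sigma = 0."""
    if sigma == 0.0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_pot(config: SimConfig) -> list[PlantCalibrationSeries]:
    """Generate pot wetting-up series for ``config.n_plants`` plants.

    Each plant draws a root dry mass uniformly from the species range; its
    true saturated capacitance follows the linear mass relation with
    multiplicative noise; every reading (including the saturated tenth)
    carries lognormal measurement noise, and the noisy saturated reading
    defines the plant's own normaliser, as in the real protocol.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.theta_grid, dtype=float)
    rdm = np.sort(rng.uniform(*config.rdm_range, size=config.n_plants))
    ages = np.round(
        np.linspace(config.age_range[0], config.age_range[1], config.n_plants)
    ).astype(int)
    prefix = "M" if config.species is Species.MAIZE else "S"
    out = []
    for i in range(config.n_plants):
        c_star = (config.mass_slope * rdm[i] + config.mass_intercept) * (
            1.0 + rng.normal(0.0, config.mass_noise)
        )
        c_star = max(c_star, 0.1)
        pid = f"{prefix}{i + 1}"
        noise = _lognorm_factor(rng, config.sigma_ln, size=len(grid))
        c_r = c_star * config.gen_a * np.exp(config.gen_b * grid) * noise
        readings = [
            CapacitanceReading(
                plant_id=pid,
                species=config.species,
                theta_rel=float(t),
                c_r=float(c),
            )
            for t, c in zip(grid, c_r)
        ]
        out.append(
            PlantCalibrationSeries(
                plant_id=pid,
                species=config.species,
                readings=readings,
                plant_age_days=int(ages[i]),
                rdm=float(rdm[i]),
            )
        )
    return out


def simulate_field(
    config: SimConfig,
) -> tuple[FieldCampaign, pd.DataFrame]:
    """Generate a field campaign plus the per-plant ground truth.

    Per day and plant: theta_rel is truncated-normal around the day mean
    (rejection sampling into (0, 1]); the plant's true C_R* is lognormal
    around the day's template mean; the measured C_R follows the
    generating calibration with lognormal measurement noise.  Soybean
    campaigns carry CON and INO treatments (n_per_day each); inoculated
    plants get a multiplicative C_R* uplift inside the uplift window.
    Returns the campaign and a ground-truth table of true per-plant C_R*.
    """
    if not config.field_days:
        raise ValueError("field_days must be non-empty")
    rng = np.random.default_rng(config.seed)
    treatments = (
        [Treatment.CON, Treatment.INO]
        if config.species is Species.SOYBEAN
        else [Treatment.NONE]
    )
    if config.n_per_day % config.n_groups:
        raise ValueError("n_per_day must be divisible by n_groups")
    per_group = config.n_per_day // config.n_groups
    readings, truth = [], []
    for day in config.field_days:
        day = day if isinstance(day, FieldDay) else FieldDay(**day)
        sd_theta = day.theta_cv * day.mean_theta
        for treatment in treatments:
            uplifted = (
                treatment is Treatment.INO
                and config.uplift_window[0] <= day.das <= config.uplift_window[1]
            )
            day_mean = day.mean_cstar * (
                1.0 + config.treatment_uplift if uplifted else 1.0
            )
            for g in range(config.n_groups):
                for j in range(per_group):
                    theta = _truncated_normal(rng, day.mean_theta, sd_theta)
                    c_star = day_mean * _lognorm_factor(rng, config.sigma_plant)
                    c_r = (
                        c_star
                        * config.gen_a
                        * math.exp(config.gen_b * theta)
                        * _lognorm_factor(rng, config.sigma_ln)
                    )
                    pid = f"d{day.das}-{treatment.value}-g{g + 1}-{j + 1}"
                    readings.append(
                        CapacitanceReading(
                            plant_id=pid,
                            species=config.species,
                            theta_rel=theta,
                            c_r=c_r,
                            das=day.das,
                            group=f"g{g + 1}",
                            treatment=treatment,
                            bbch=day.bbch,
                        )
                    )
                    truth.append(
                        {
                            "plant_id": pid,
                            "das": day.das,
                            "treatment": treatment.value,
                            "c_star_true": c_star,
                            "day_mean_cstar": day_mean,
                        }
                    )
    return FieldCampaign(species=config.species, readings=readings), pd.DataFrame(truth)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float = 1e-6, hi: float = 1.0
) -> float:
    """Normal draw rejected into (lo, hi]; keeps theta_rel physical."""
    if sd == 0.0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def simulate_soil(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate (theta_rel, C_S) pairs from the soil power law.

    n pairs with theta_rel uniform on the configured range and lognormal
    multiplicative noise on C_S.
    """
    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(*config.soil_theta_range, size=config.soil_n)
    c_s = (
        config.soil_coeff
        * theta**config.soil_expnt
        * _lognorm_factor(rng, config.soil_sigma, size=config.soil_n)
    )
    return theta, c_s


def _logistic(x: float, low: float, high: float, rate: float, mid: float) -> float:
    return low + (high - low) / (1.0 + math.exp(-rate * (x - mid)))


def simulate_harvest(config: SimConfig) -> list[HarvestRecord]:
    """Generate destructive-sampling records for the soybean field trial.

    Shoot dry mass grows along a logistic curve to the configured final
    mean; inoculated plants get the biomass uplift inside the uplift
    window.  AMF colonization intensity is low (~20%) before pod filling
    and rises to ~80% at ripening, for both treatments.  Grain dry mass is
    recorded at the final harvest only.
    """
    rng = np.random.default_rng(config.seed)
    sdm_sigma = math.sqrt(math.log(1.0 + config.sdm_cv**2))
    records = []
    schedule = [(d, config.plants_per_plot) for d in config.harvest_days]
    schedule.append((config.final_day, config.final_per_plot))
    for das, per_plot in schedule:
        sdm_mean = config.sdm_final / (
            1.0 + math.exp(-config.sdm_growth_rate * (das - config.sdm_midpoint))
        )
        m_mean = _logistic(
            das, config.m_low, config.m_high, config.m_rise_rate, config.m_midpoint
        )
        in_window = config.uplift_window[0] <= das <= config.uplift_window[1]
        for treatment in (Treatment.CON, Treatment.INO):
            t_sdm = sdm_mean * (
                1.0 + config.sdm_uplift
                if treatment is Treatment.INO and in_window
                else 1.0
            )
            t_m = m_mean + (
                config.m_uplift_pts
                if treatment is Treatment.INO and in_window
                else 0.0
            )
            for plot in range(config.n_plots):
                for j in range(per_plot):
                    # mean-preserving lognormal: E[sdm] = t_sdm
                    sdm = t_sdm * math.exp(
                        rng.normal(-0.5 * sdm_sigma**2, sdm_sigma)
                    )
                    m_pct = float(
                        np.clip(rng.normal(t_m, config.m_sd), 0.0, 100.0)
                    )
                    grain = None
                    if das == config.final_day:
                        grain = max(
                            0.0,
                            config.grain_frac
                            * sdm
                            * (1.0 + rng.normal(0.0, 0.10)),
                        )
                    records.append(
                        HarvestRecord(
                            plant_id=f"h{das}-{treatment.value}-p{plot + 1}-{j + 1}",
                            das=das,
                            treatment=treatment,
                            sdm=sdm,
                            grain_dm=grain,
                            m_pct=m_pct,
                        )
                    )
    return records
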