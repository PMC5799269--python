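"""Fitting the capacitance–moisture calibration functions.

A pot wetting-up experiment yields, per plant, ~10 readings of root
capacitance C_R across relative soil water saturation theta_rel, ending in
water-saturated soil.  Dividing by the saturated reading gives the relative
capacitance C_rel, which follows

    C_rel = a * exp(b * theta_rel)

with species-specific constants.  All fitting happens on the natural-log
scale (OLS of ln C_rel on theta_rel): the exponential model is exactly
linear there, R-squared values quoted for these calibrations are ln-scale,
and no nonlinear least squares is involved.

The pooled species fit defaults to two-stage aggregation (per-plant OLS,
then precision-weighted mean of coefficients), which treats the plant as
the unit of replication — equivalent in expectation to a random-intercept
model and exactly testable.  A full mixed-model path (statsmodels MixedLM,
random plant intercept) is available via ``method="mixed"``.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    LinearMassCalibration,
    MoistureCondition,
    PlantCalibration,
    PlantCalibrationSeries,
    SoilCapacitanceModel,
    Species,
    SpeciesCalibration,
)


class FitError(ValueError):
    """Insufficient or degenerate data for a regression fit."""


def compute_c_rel(series: PlantCalibrationSeries) -> list[tuple[float, float]]:
    """Normalise a pot series to relative capacitance.

    Returns (theta_rel, c_rel) pairs with c_rel = C_R / C_R_sat, where
    C_R_sat is the plant's own reading in water-saturated soil.  The last
    pair is exactly (1.0, 1.0).
    """
    sat = series.c_r_sat
    if not sat > 0:
        raise FitError(f"plant {series.plant_id}: invalid saturated reading")
    pairs = [(r.theta_rel, r.c_r / sat) for r in series.readings]
    # guard: the saturated point defines the normaliser
    assert pairs[-1] == (1.0, 1.0)
    return pairs


def _ln_linear_fit(x: np.ndarray, ln_y: np.ndarray):
    """OLS of ln_y on x; returns slope, intercept, r2, se_slope, se_intercept."""
    n = len(x)
    if n < 3 or len(np.unique(x)) < 3:
        raise FitError(f"need >=3 distinct x values, got {len(np.unique(x))}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FitError("zero variance in x")
    res = stats.linregress(x, ln_y)
    resid = ln_y - (res.intercept + res.slope * x)
    dof = n - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    se_slope = math.sqrt(sigma2 / sxx)
    se_int = math.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))
    sst = float(np.sum((ln_y - ln_y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - float(resid @ resid) / sst
    return res.slope, res.intercept, r2, se_slope, se_int, res.pvalue


def fit_plant(series: PlantCalibrationSeries) -> PlantCalibration:
    """Fit one plant's C_rel = a_i * exp(b_i * theta_rel) on the ln scale."""
    pairs = compute_c_rel(series)
    theta = np.array([t for t, _ in pairs])
    ln_crel = np.log([c for _, c in pairs])
    slope, intercept, r2, se_b, se_a, _ = _ln_linear_fit(theta, ln_crel)
    return PlantCalibration(
        plant_id=series.plant_id,
        a_i=math.exp(intercept),
        b_i=slope,
        r2_ln=max(0.0, min(1.0, r2)),
        c_r_sat=series.c_r_sat,
        se_ln_a=se_a,
        se_b=se_b,
    )


def fit_species(
    plants: Sequence[PlantCalibrationSeries],
    method: str = "two_stage",
) -> SpeciesCalibration:
    """Pool per-plant calibrations into a species-level (a, b).

    ``method="two_stage"`` (default): per-plant ln-scale OLS, then a
    precision-weighted (inverse squared standard error) mean of slopes and
    intercepts; noise-free fits fall back to an unweighted mean.
    ``method="mixed"``: ln-scale linear mixed model with a random plant
    intercept (REML).  Both return k = 1/a at full precision and the pooled
    ln-scale R-squared of the fixed-effect line.
    """
    if len(plants) < 2:
        raise FitError("need >= 2 plants for a pooled fit")
    species = plants[0].species
    if any(p.species != species for p in plants):
        raise FitError("heterogeneous species in pooled fit")

    theta_all, ln_all, plant_ids = [], [], []
    for p in plants:
        for t, c in compute_c_rel(p):
            theta_all.append(t)
            ln_all.append(math.log(c))
            plant_ids.append(p.plant_id)
    theta_all = np.array(theta_all)
    ln_all = np.array(ln_all)
    n_obs = len(theta_all)

    if method == "two_stage":
        fits = [fit_plant(p) for p in plants]
        slopes = np.array([f.b_i for f in fits])
        lnas = np.log([f.a_i for f in fits])
        se_b = np.array([f.se_b for f in fits])
        se_a = np.array([f.se_ln_a for f in fits])
        if np.all(se_b > 1e-12):
            wb, wa = 1.0 / se_b**2, 1.0 / se_a**2
            b = float(np.sum(wb * slopes) / np.sum(wb))
            ln_a = float(np.sum(wa * lnas) / np.sum(wa))
        else:  # perfect per-plant fits: plain mean
            b = float(slopes.mean())
            ln_a = float(lnas.mean())
    elif method == "mixed":
        import statsmodels.formula.api as smf

        df = pd.DataFrame(
            {"ln_crel": ln_all, "theta_rel": theta_all, "plant": plant_ids}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("ln_crel ~ theta_rel", df, groups=df["plant"]).fit()
        ln_a = float(fit.params["Intercept"])
        b = float(fit.params["theta_rel"])
    else:
        raise ValueError(f"unknown method {method!r}")

    pred = ln_a + b * theta_all
    sse = float(np.sum((ln_all - pred) ** 2))
    sst = float(np.sum((ln_all - ln_all.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    r2_adj = 1.0 if sst == 0.0 else 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - 2)
    return SpeciesCalibration(
        species=species,
        a=math.exp(ln_a),
        b=b,
        r2=r2,
        r2_adj=r2_adj,
        n_obs=n_obs,
        n_plants=len(plants),
    )


# ---------------------------------------------------------------------------
# Age / species effects on the calibration (mixed-model term tests)

_EFFECT_TERMS = [
    "theta_rel",
    "age",
    "species",
    "theta_rel:age",
    "theta_rel:species",
    "age:species",
    "theta_rel:age:species",
]


def _effects_frame(plants: Sequence[PlantCalibrationSeries]) -> pd.DataFrame:
    rows = []
    for p in plants:
        if p.plant_age_days is None:
            raise FitError(f"plant {p.plant_id}: plant_age_days required")
        for t, c in compute_c_rel(p):
            rows.append(
                {
                    "ln_crel": math.log(c),
                    "theta_rel": t,
                    "age": float(p.plant_age_days),
                    "species": p.species.value,
                    "plant": f"{p.species.value}:{p.plant_id}",
                }
            )
    return pd.DataFrame(rows)


def test_age_species_effects(
    maize_plants: Sequence[PlantCalibrationSeries],
    soybean_plants: Sequence[PlantCalibrationSeries],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test whether plant age and species shift the C_rel–theta_rel curve.

    Fits linear mixed models of ln C_rel on theta_rel x age x species with
    a random plant intercept (ML), adding one term at a time in the
    canonical order (main effects, then two-way, then three-way
    interactions) and reports the sequential likelihood-ratio chi-square
    statistic and p-value per term — the nested-model ANOVA convention for
    mixed models.  Age is centred and scaled within the pooled data.  If
    age is constant, age terms are dropped with a warning.

    Returns a DataFrame with columns ``term, statistic, p_value,
    significant`` (significance at ``alpha``).
    """
    if not maize_plants or not soybean_plants:
        raise FitError("both species required")
    sp_m = {p.species for p in maize_plants}
    sp_s = {p.species for p in soybean_plants}
    if sp_m == sp_s:
        raise FitError("the two plant lists must hold different species")

    df = _effects_frame(list(maize_plants) + list(soybean_plants))
    # centre and scale age: keeps the interaction design well conditioned
    df["age"] = df["age"] - df["age"].mean()
    age_scale = df["age"].std()
    if age_scale > 0:
        df["age"] = df["age"] / age_scale

    terms = list(_EFFECT_TERMS)
    if df.groupby("species")["age"].nunique().min() < 2:
        warnings.warn("constant plant age: age terms dropped from the model")
        terms = [t for t in terms if "age" not in t]

    import statsmodels.formula.api as smf

    def _ml_fit(model_terms):
        formula = "ln_crel ~ " + " + ".join(model_terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["plant"])
            for fit_method in ("bfgs", "lbfgs", "cg"):
                try:
                    return model.fit(reml=False, method=fit_method)
                except np.linalg.LinAlgError:
                    continue
            raise FitError("mixed model did not converge under any optimizer")

    rows = []
    prev = _ml_fit(["1"])
    for i, term in enumerate(terms):
        fit = _ml_fit(terms[: i + 1])
        lr = max(2.0 * (fit.llf - prev.llf), 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        rows.append(
            {
                "term": term,
                "statistic": lr,
                "p_value": p,
                "significant": p < alpha,
            }
        )
        prev = fit
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Auxiliary calibrations

def fit_mass_calibration(
    c_r: Sequence[float],
    rdm: Sequence[float],
    condition: MoistureCondition | str,
) -> LinearMassCalibration:
    """OLS of root capacitance (nF) on root dry mass (g) at one moisture level."""
    c_r = np.asarray(c_r, dtype=float)
    rdm = np.asarray(rdm, dtype=float)
    if len(c_r) != len(rdm):
        raise FitError(f"length mismatch: {len(c_r)} c_r vs {len(rdm)} rdm")
    if len(c_r) < 3:
        raise FitError("need >= 3 points")
    if np.ptp(rdm) == 0:
        raise FitError("zero variance in rdm")
    res = stats.linregress(rdm, c_r)
    return LinearMassCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        condition=MoistureCondition(condition),
    )


def fit_soil_model(
    theta_rel: Sequence[float], c_s: Sequence[float]
) -> SoilCapacitanceModel:
    """Fit the soil-capacitance power law C_S = coeff * theta_rel ** expnt.

    Linearised as OLS of ln C_S on ln theta_rel; coeff = exp(intercept),
    expnt = slope, R-squared on the ln scale.
    """
    theta_rel = np.asarray(theta_rel, dtype=float)
    c_s = np.asarray(c_s, dtype=float)
    if np.any(theta_rel <= 0) or np.any(c_s <= 0):
        raise FitError("power-law fit requires strictly positive values")
    slope, intercept, r2, _, _, _ = _ln_linear_fit(
        np.log(theta_rel), np.log(c_s)
    )
    return SoilCapacitanceModel(
        coeff=math.exp(intercept), expnt=slope, r2=max(0.0, min(1.0, r2))
    )
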