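"""Domain types and CSV / config I/O for root-capacitance pipelines.

The atomic datum everywhere is a single (plant, time, theta_rel, C_R)
observation: ``theta_rel`` is the relative water saturation of the soil
around the root system (volumetric soil water content divided by the
saturation water content) and ``c_r`` is the parallel electrical
capacitance in nanofarads measured between a ground electrode in the soil
and a clamp on the plant stem.

CSV is the single interchange format, one row per reading.  Recognised
columns: ``plant_id, species, das, group, treatment, theta_rel | swc_vol,
c_r_nf, bbch`` plus ``plant_age_days`` and ``rdm_g`` for pot-calibration
files and ``sdm_g, grain_dm_g, m_pct`` for harvest files.  Volumetric soil
water content (``swc_vol``) is converted to ``theta_rel`` at ingest and
never downstream, so the saturation constant enters the pipeline in exactly
one place.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: theta_rel marginally above 1 (instrument noise around saturation) is
#: clamped to 1; anything above this factor is a hard validation error.
THETA_CLAMP_MAX = 1.02


class Species(str, enum.Enum):
    MAIZE = "maize"
    SOYBEAN = "soybean"


class Treatment(str, enum.Enum):
    CON = "CON"
    INO = "INO"
    NONE = "none"


class ValidationError(ValueError):
    """A record violates a type invariant; message carries row indices."""


class SchemaError(ValueError):
    """A CSV file lacks columns required by the requested schema."""


@dataclass(frozen=True)
class SoilWaterConstants:
    """Water-retention constants of the experimental soil (cm^3 cm^-3).

    Defaults are the chernozem soil used for both the pot calibration and
    the field trials: saturation 0.476, field capacity 0.305, permanent
    wilting point 0.097.
    """

    sat_wc: float = 0.476
    field_capacity: float = 0.305
    wilting_point: float = 0.097

    def __post_init__(self) -> None:
        if not (0.0 < self.wilting_point < self.field_capacity < self.sat_wc):
            raise ValidationError(
                "require 0 < wilting_point < field_capacity < sat_wc, got "
                f"{self.wilting_point}, {self.field_capacity}, {self.sat_wc}"
            )

    def to_theta_rel(self, swc_vol: float) -> float:
        """Convert volumetric soil water content to relative saturation."""
        return swc_vol / self.sat_wc


@dataclass
class CapacitanceReading:
    plant_id: str
    species: Species
    theta_rel: float
    c_r: float  # nF, > 0
    das: Optional[int] = None  # days after sowing
    group: Optional[str] = None  # plot / row-segment label
    treatment: Treatment = Treatment.NONE
    bbch: Optional[int] = None

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        self.treatment = Treatment(self.treatment)
        if not (0.0 <= self.theta_rel <= 1.0):
            raise ValidationError(
                f"theta_rel must be in [0, 1], got {self.theta_rel!r} "
                f"(plant {self.plant_id})"
            )
        if not self.c_r > 0:
            raise ValidationError(
                f"c_r must be > 0 nF, got {self.c_r!r} (plant {self.plant_id})"
            )
        if self.das is not None and self.das < 0:
            raise ValidationError(f"das must be >= 0, got {self.das!r}")


@dataclass
class PlantCalibrationSeries:
    """One pot plant's wetting-up series, ending in water-saturated soil.

    The last reading, taken at theta_rel = 1, defines the plant's own
    saturation capacitance C_R* used to normalise the series to relative
    capacitance C_rel = C_R / C_R*.
    """

    plant_id: str
    species: Species
    readings: list[CapacitanceReading]
    plant_age_days: Optional[int] = None
    rdm: Optional[float] = None  # root dry mass, g

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        if not self.readings:
            raise ValidationError(f"plant {self.plant_id}: empty series")
        for r in self.readings:
            if r.plant_id != self.plant_id or r.species != self.species:
                raise ValidationError(
                    f"plant {self.plant_id}: reading belongs to "
                    f"{r.plant_id}/{r.species.value}"
                )
        thetas = [r.theta_rel for r in self.readings]
        if any(b <= a for a, b in zip(thetas, thetas[1:])):
            raise ValidationError(
                f"plant {self.plant_id}: theta_rel not strictly increasing "
                "(wetting-up protocol)"
            )
        if thetas[-1] != 1.0:
            raise ValidationError(
                f"plant {self.plant_id}: series must end at theta_rel = 1 "
                f"(saturated reading), last theta_rel = {thetas[-1]}"
            )
        if self.rdm is not None and self.rdm < 0:
            raise ValidationError(f"plant {self.plant_id}: rdm < 0")

    @property
    def c_r_sat(self) -> float:
        """Capacitance in water-saturated soil (the plant's C_R*)."""
        return self.readings[-1].c_r


@dataclass
class PlantCalibration:
    """Per-plant exponential fit C_rel = a_i * exp(b_i * theta_rel)."""

    plant_id: str
    a_i: float
    b_i: float
    r2_ln: float  # R^2 of the ln-scale linear fit
    c_r_sat: float
    se_ln_a: float = float("nan")
    se_b: float = float("nan")

    def __post_init__(self) -> None:
        if not self.a_i > 0:
            raise ValidationError(f"a_i must be > 0, got {self.a_i}")
        if not (0.0 <= self.r2_ln <= 1.0 + 1e-12):
            raise ValidationError(f"r2_ln outside [0, 1]: {self.r2_ln}")


@dataclass
class SpeciesCalibration:
    """Pooled species-level calibration C_rel = a * exp(b * theta_rel).

    ``k = 1/a`` is the inversion constant of the apparent-capacitance
    formula C_R* = C_R * k * exp(-b * theta_rel).  When ``k`` is not given
    it is computed from ``a`` at full precision; presets built from
    published rounded constants may override it (see
    :mod:`rootcap.normalization`), in which case k*a can differ from 1 by
    up to the rounding error of the source.
    """

    species: Species
    a: float
    b: float
    k: Optional[float] = None
    r2: Optional[float] = None
    r2_adj: Optional[float] = None
    n_obs: int = 0
    n_plants: int = 0

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        if not self.a > 0:
            raise ValidationError(f"a must be > 0, got {self.a}")
        if self.k is None:
            self.k = 1.0 / self.a
        elif not math.isclose(self.k * self.a, 1.0, rel_tol=5e-3):
            raise ValidationError(
                f"inversion constant k={self.k} inconsistent with a={self.a}"
            )
        sat = self.a * math.exp(self.b)
        if abs(sat - 1.0) > 0.05:
            logger.warning(
                "calibration a*e^b = %.4f deviates >5%% from 1: "
                "C_rel at saturation should be ~1 by construction", sat,
            )

    def c_rel(self, theta_rel: float) -> float:
        """Predicted relative capacitance at a given saturation."""
        return self.a * math.exp(self.b * theta_rel)


@dataclass
class SoilCapacitanceModel:
    """Power law C_S = coeff * theta_rel ** expnt for soil capacitance (nF)."""

    coeff: float
    expnt: float
    r2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.coeff > 0 and self.expnt > 0):
            raise ValidationError("soil model requires coeff > 0 and expnt > 0")

    def predict(self, theta_rel):
        import numpy as np

        return self.coeff * np.asarray(theta_rel, dtype=float) ** self.expnt


class MoistureCondition(str, enum.Enum):
    WILTING_POINT = "wilting_point"
    SATURATED = "saturated"


@dataclass
class LinearMassCalibration:
    """Linear C_R (nF) vs root dry mass (g) calibration at one moisture level."""

    slope: float  # nF per gram
    intercept: float  # nF
    r2: float
    condition: MoistureCondition

    def __post_init__(self) -> None:
        self.condition = MoistureCondition(self.condition)


@dataclass
class HarvestRecord:
    plant_id: str
    das: int
    treatment: Treatment
    sdm: float  # shoot dry mass, g
    grain_dm: Optional[float] = None
    m_pct: Optional[float] = None  # AMF colonization intensity, %

    def __post_init__(self) -> None:
        self.treatment = Treatment(self.treatment)
        if self.sdm < 0:
            raise ValidationError(f"plant {self.plant_id}: sdm < 0")
        if self.m_pct is not None and not (0.0 <= self.m_pct <= 100.0):
            raise ValidationError(
                f"plant {self.plant_id}: m_pct outside [0, 100]: {self.m_pct}"
            )


@dataclass
class FieldCampaign:
    """All field readings of one species across measurement days."""

    species: Species
    readings: list[CapacitanceReading] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        for r in self.readings:
            if r.species != self.species:
                raise ValidationError(
                    f"campaign species {self.species.value} but reading of "
                    f"{r.species.value}"
                )

    @property
    def days(self) -> list[int]:
        return sorted({r.das for r in self.readings if r.das is not None})


# ---------------------------------------------------------------------------
# CSV ingest

_SCHEMA_REQUIRED = {
    "pot": {"plant_id", "species", "c_r_nf"},
    "field": {"plant_id", "species", "das", "c_r_nf"},
    "harvest": {"plant_id", "das", "treatment", "sdm_g"},
}


def _resolve_theta(
    df: pd.DataFrame, constants: Optional[SoilWaterConstants]
) -> pd.Series:
    if "theta_rel" in df.columns:
        theta = df["theta_rel"].astype(float)
    elif "swc_vol" in df.columns:
        constants = constants or SoilWaterConstants()
        theta = df["swc_vol"].astype(float) / constants.sat_wc
    else:
        raise SchemaError("need a theta_rel or swc_vol column")
    # saturation is a physical ceiling: small overshoot is instrument noise
    over = (theta > 1.0) & (theta <= THETA_CLAMP_MAX)
    if over.any():
        logger.warning(
            "clamping %d theta_rel values in (1, %.2f] to 1 (rows %s)",
            int(over.sum()), THETA_CLAMP_MAX, list(df.index[over]),
        )
        theta = theta.where(~over, 1.0)
    bad = (theta < 0) | (theta > 1.0)
    if bad.any():
        raise ValidationError(
            f"theta_rel outside [0, 1] after conversion at rows "
            f"{list(df.index[bad])}"
        )
    return theta


def read_readings(
    path: str | Path,
    schema: str,
    soil_constants: Optional[SoilWaterConstants] = None,
) -> list:
    """Read and validate a CSV of instrument readings or harvest records.

    ``schema`` is one of ``"pot"``, ``"field"``, ``"harvest"``.  Pot and
    field files yield :class:`CapacitanceReading`; harvest files yield
    :class:`HarvestRecord`.  Rows violating type invariants raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    if schema not in _SCHEMA_REQUIRED:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    missing = _SCHEMA_REQUIRED[schema] - set(df.columns)
    if schema in ("pot", "field") and missing == set():
        if "theta_rel" not in df.columns and "swc_vol" not in df.columns:
            missing = {"theta_rel|swc_vol"}
    if missing:
        raise SchemaError(
            f"{path.name}: schema {schema!r} requires columns {sorted(missing)}"
        )

    if schema == "harvest":
        records = []
        for idx, row in df.iterrows():
            try:
                records.append(
                    HarvestRecord(
                        plant_id=str(row["plant_id"]),
                        das=int(row["das"]),
                        treatment=Treatment(row["treatment"]),
                        sdm=float(row["sdm_g"]),
                        grain_dm=_opt_float(row.get("grain_dm_g")),
                        m_pct=_opt_float(row.get("m_pct")),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path.name} row {idx}: {exc}") from exc
        return records

    theta = _resolve_theta(df, soil_constants)
    readings = []
    for idx, row in df.iterrows():
        try:
            readings.append(
                CapacitanceReading(
                    plant_id=str(row["plant_id"]),
                    species=Species(row["species"]),
                    theta_rel=float(theta.loc[idx]),
                    c_r=float(row["c_r_nf"]),
                    das=_opt_int(row.get("das")),
                    group=_opt_str(row.get("group")),
                    treatment=Treatment(row["treatment"])
                    if _opt_str(row.get("treatment"))
                    else Treatment.NONE,
                    bbch=_opt_int(row.get("bbch")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path.name} row {idx}: {exc}") from exc
    return readings


def read_pot_series(
    path: str | Path,
    soil_constants: Optional[SoilWaterConstants] = None,
) -> list[PlantCalibrationSeries]:
    """Read a pot-calibration CSV and group rows into per-plant series.

    Rows must appear in measurement order within each plant (the wetting-up
    protocol: strictly increasing theta_rel, saturated reading last).
    Optional per-plant columns ``plant_age_days`` and ``rdm_g`` are carried
    onto the series.
    """
    path = Path(path)
    df = pd.read_csv(path)
    readings = read_readings(path, "pot", soil_constants)
    by_plant: dict[str, list[CapacitanceReading]] = {}
    for r in readings:
        by_plant.setdefault(r.plant_id, []).append(r)
    meta = df.drop_duplicates("plant_id").set_index(
        df.drop_duplicates("plant_id")["plant_id"].astype(str)
    )
    series = []
    for pid, rs in by_plant.items():
        row = meta.loc[pid]
        series.append(
            PlantCalibrationSeries(
                plant_id=pid,
                species=rs[0].species,
                readings=rs,
                plant_age_days=_opt_int(row.get("plant_age_days")),
                rdm=_opt_float(row.get("rdm_g")),
            )
        )
    return series


# ---------------------------------------------------------------------------
# CSV output

def write_summary(records: Sequence, path: str | Path) -> Path:
    """Write a list of dataclass records (e.g. day summaries) to CSV.

    Round-trip stable on all typed fields: ``read_summary(write_summary(x))``
    reproduces the input.  Refuses to write an empty file.
    """
    if not records:
        raise ValueError("refusing to write an empty summary")
    rows = []
    for rec in records:
        d = asdict(rec)
        for key, val in d.items():
            if isinstance(val, enum.Enum):
                d[key] = val.value
        rows.append(d)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_summary(path: str | Path, record_type):
    """Re-parse a CSV written by :func:`write_summary` into typed records."""
    df = pd.read_csv(path)
    out = []
    type_hints = {f.name: f.type for f in fields(record_type)}
    for _, row in df.iterrows():
        kwargs = {}
        for name in type_hints:
            if name not in df.columns:
                continue
            val = row[name]
            if pd.isna(val):
                val = None
            elif isinstance(val, float) and float(val).is_integer() and (
                "int" in str(type_hints[name]).lower()
            ):
                val = int(val)
            kwargs[name] = val
        out.append(record_type(**kwargs))
    return out


def readings_to_frame(readings: Iterable[CapacitanceReading]) -> pd.DataFrame:
    """Flatten readings to the canonical CSV column layout."""
    rows = [
        {
            "plant_id": r.plant_id,
            "species": r.species.value,
            "das": r.das,
            "group": r.group,
            "treatment": r.treatment.value,
            "theta_rel": r.theta_rel,
            "c_r_nf": r.c_r,
            "bbch": r.bbch,
        }
        for r in readings
    ]
    return pd.DataFrame(rows)


def write_readings(readings: Sequence[CapacitanceReading], path: str | Path) -> Path:
    if not readings:
        raise ValueError("refusing to write an empty readings file")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    readings_to_frame(readings).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Config I/O (YAML)

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def _opt_float(val) -> Optional[float]:
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    try:
        if pd.isna(val):
            return None
    except (TypeError, ValueError):
        pass
    return float(val)


def _opt_int(val) -> Optional[int]:
    f = _opt_float(val)
    return None if f is None else int(f)


def _opt_str(val) -> Optional[str]:
    if val is None:
        return None
    try:
        if pd.isna(val):
            return None
    except (TypeError, ValueError):
        pass
    s = str(val)
    return s if s else None
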