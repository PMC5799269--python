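"""Field-campaign statistics on normalised capacitance readings.

Covers the field workflow around C_R*: replicate-group homogeneity checks
before pooling, per-day mean/SD/CV summaries, change tests between
consecutive measurement days, control-vs-inoculated treatment comparisons,
per-day exponential C_R–theta_rel regressions, and multi-group harvest
comparisons (shoot dry mass, AMF colonization intensity).

Test selection follows the classical gate: a variance-equality pre-test
(F-test for two groups, Bartlett for more) at alpha = 0.05 chooses Student
vs Welch t (two groups) and one-way ANOVA + Tukey–Kramer vs
Kruskal–Wallis + Dunn (three or more).  Significance stars use strict
cutoffs: *** p < 0.001, ** p < 0.01, * p < 0.05, otherwise NS.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import FitError, _ln_linear_fit

ALPHA_VARIANCE_GATE = 0.05


class TestKind(str, enum.Enum):
    CONSECUTIVE_DAY = "consecutive_day"
    TREATMENT = "treatment"
    MULTI_GROUP = "multi_group"


class TestUsed(str, enum.Enum):
    T = "t"
    WELCH_T = "welch_t"
    ANOVA = "anova"
    ANOVA_TUKEY = "anova_tukey"
    KRUSKAL_DUNN = "kruskal_dunn"


def significance_stars(p: float) -> str:
    """Map a p-value to stars with strict thresholds; p = 0.05 is NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class ComparisonResult:
    kind: TestKind
    statistic: float
    p_value: float
    test_used: TestUsed
    stars: str = ""
    pooling_recommended: Optional[bool] = None
    posthoc: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = significance_stars(self.p_value)


@dataclass
class DaySummary:
    """Per-measurement-day statistics of C_R* and theta_rel (mean, SD, CV%)."""

    das: int
    treatment: str
    n: int
    mean_c_star: float
    sd_c_star: float
    cv_pct: float
    mean_theta: float
    sd_theta: float
    bbch: Optional[int] = None


@dataclass
class DayRegression:
    """Within-day exponential C_R ~ exp(b * theta_rel) regression."""

    das: int
    a_day: float
    b_day: float
    r2: float
    p_value: float
    n: int


def summarize_day(
    c_star: Sequence[float],
    theta: Sequence[float],
    das: int,
    treatment: str = "none",
    bbch: Optional[int] = None,
) -> DaySummary:
    """Mean, sample SD (n-1) and CV% of one day's C_R* and theta_rel."""
    c = np.asarray(c_star, dtype=float)
    t = np.asarray(theta, dtype=float)
    if len(c) < 2:
        raise ValueError("need n >= 2 readings for a day summary")
    mean_c = float(c.mean())
    sd_c = float(c.std(ddof=1))
    return DaySummary(
        das=int(das),
        treatment=str(treatment),
        n=len(c),
        mean_c_star=mean_c,
        sd_c_star=sd_c,
        cv_pct=100.0 * sd_c / mean_c if mean_c != 0 else float("nan"),
        mean_theta=float(t.mean()),
        sd_theta=float(t.std(ddof=1)),
        bbch=bbch,
    )


def check_poolability(groups: Sequence[Sequence[float]]) -> ComparisonResult:
    """One-way ANOVA across replicate groups; pool iff p >= 0.05.

    Used on theta_rel and C_R across the replicate row-segments/plots of a
    measurement day before merging them into a single n=48 sample.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    if all(len(g) == len(arrays[0]) and np.allclose(g, arrays[0]) for g in arrays):
        # identical copies: zero between-group variance
        return ComparisonResult(
            kind=TestKind.MULTI_GROUP,
            statistic=0.0,
            p_value=1.0,
            test_used=TestUsed.ANOVA,
            pooling_recommended=True,
        )
    f, p = stats.f_oneway(*arrays)
    return ComparisonResult(
        kind=TestKind.MULTI_GROUP,
        statistic=float(f),
        p_value=float(p),
        test_used=TestUsed.ANOVA,
        pooling_recommended=bool(p >= 0.05),
    )


def _variances_differ(a: np.ndarray, b: np.ndarray) -> tuple[bool, float]:
    """Two-sided F-test on the variance ratio of two samples."""
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return False, 1.0
    if v2 == 0.0 or v1 == 0.0:
        return True, 0.0
    f = v1 / v2
    d1, d2 = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
    p = min(p, 1.0)
    return p < ALPHA_VARIANCE_GATE, p


def _two_sample(
    a: Sequence[float], b: Sequence[float], kind: TestKind
) -> ComparisonResult:
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 in both samples")
    if len(x) == len(y) and np.allclose(np.sort(x), np.sort(y)) and x.var() == 0:
        # identical constant samples: no evidence of change
        return ComparisonResult(kind, 0.0, 1.0, TestUsed.T)
    unequal, _ = _variances_differ(x, y)
    res = stats.ttest_ind(x, y, equal_var=not unequal)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both, equal means
        p = 1.0
    return ComparisonResult(
        kind=kind,
        statistic=float(res.statistic) if not math.isnan(res.statistic) else 0.0,
        p_value=p,
        test_used=TestUsed.WELCH_T if unequal else TestUsed.T,
    )


def compare_consecutive(
    day_a: Sequence[float], day_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided test of C_R* change between two consecutive days.

    The variance pre-test selects Student vs Welch; symmetric in its
    arguments.
    """
    return _two_sample(day_a, day_b, TestKind.CONSECUTIVE_DAY)


def compare_treatments(
    con: Sequence[float], ino: Sequence[float]
) -> ComparisonResult:
    """Two-sided control-vs-inoculated comparison (same gate as above)."""
    return _two_sample(con, ino, TestKind.TREATMENT)


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1) / 12.0 - ties / (12.0 * (n_total - 1))
    mean_ranks, sizes, offset = [], [], 0
    for g in groups:
        mean_ranks.append(float(ranks[offset : offset + len(g)].mean()))
        sizes.append(len(g))
        offset += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)  # Bonferroni
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": z,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def _tukey_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons (handles unequal group sizes)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labs = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    res = pairwise_tukeyhsd(values, labs, alpha=0.05)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame = frame.rename(
        columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_value"}
    )
    frame["stars"] = [significance_stars(float(p)) for p in frame["p_value"]]
    return frame[["group_a", "group_b", "meandiff", "p_value", "stars"]]


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Omnibus comparison of >= 3 groups with post-hoc pairwise tests.

    Bartlett's test at alpha = 0.05 gates between one-way ANOVA with a
    Tukey–Kramer post-test (homogeneous variances) and Kruskal–Wallis with
    a Bonferroni-adjusted Dunn post-test.  Used for harvest shoot dry mass
    and AMF colonization across sampling occasions/treatments.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("compare_groups needs >= 3 groups (else use the t path)")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    labels = list(labels) if labels is not None else [
        f"g{i}" for i in range(len(arrays))
    ]
    _, p_bart = stats.bartlett(*arrays)
    if p_bart < ALPHA_VARIANCE_GATE:
        h, p = stats.kruskal(*arrays)
        posthoc = _dunn_posthoc(arrays, labels)
        used = TestUsed.KRUSKAL_DUNN
        statistic = float(h)
    else:
        f, p = stats.f_oneway(*arrays)
        posthoc = _tukey_posthoc(arrays, labels)
        used = TestUsed.ANOVA_TUKEY
        statistic = float(f)
    return ComparisonResult(
        kind=TestKind.MULTI_GROUP,
        statistic=statistic,
        p_value=float(p),
        test_used=used,
        posthoc=posthoc,
    )


def day_cr_theta_regression(
    theta: Sequence[float], c_r: Sequence[float], das: int = -1
) -> DayRegression:
    """Within-day exponential C_R–theta_rel regression across plants.

    OLS of ln C_R on theta_rel for the readings of a single measurement
    day; returns the natural-scale intercept a_day = exp(intercept), the
    slope b_day, ln-scale R² and the slope p-value.
    """
    theta = np.asarray(theta, dtype=float)
    c_r = np.asarray(c_r, dtype=float)
    if len(theta) < 5:
        raise FitError("need n >= 5 readings for a day regression")
    if np.ptp(theta) == 0:
        raise FitError("degenerate theta_rel spread within the day")
    slope, intercept, r2, _, _, pval = _ln_linear_fit(theta, np.log(c_r))
    return DayRegression(
        das=int(das),
        a_day=math.exp(intercept),
        b_day=float(slope),
        r2=max(0.0, min(1.0, r2)),
        p_value=float(pval),
        n=len(theta),
    )


# ---------------------------------------------------------------------------
# Campaign-level drivers over the normalized table

def summarize_campaign(normalized: pd.DataFrame) -> list[DaySummary]:
    """Per-(day, treatment) summaries from a normalize_campaign table."""
    out = []
    for (das, treatment), sub in normalized.groupby(
        ["das", "treatment"], dropna=False, sort=True
    ):
        bbch = sub["bbch"].dropna()
        out.append(
            summarize_day(
                sub["c_r_star_nf"],
                sub["theta_rel"],
                das=int(das),
                treatment=str(treatment),
                bbch=int(bbch.iloc[0]) if len(bbch) else None,
            )
        )
    return out


def consecutive_day_tests(
    normalized: pd.DataFrame, treatment: Optional[str] = None
) -> pd.DataFrame:
    """C_R* change tests between every pair of consecutive measurement days."""
    df = normalized
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    days = sorted(df["das"].dropna().unique())
    rows = []
    for d1, d2 in zip(days, days[1:]):
        res = compare_consecutive(
            df.loc[df["das"] == d1, "c_r_star_nf"],
            df.loc[df["das"] == d2, "c_r_star_nf"],
        )
        rows.append(
            {
                "das_a": int(d1),
                "das_b": int(d2),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "test_used": res.test_used.value,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)


def treatment_tests(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-day CON vs INO comparisons of C_R* over a two-treatment campaign."""
    rows = []
    for das in sorted(normalized["das"].dropna().unique()):
        sub = normalized[normalized["das"] == das]
        con = sub.loc[sub["treatment"] == "CON", "c_r_star_nf"]
        ino = sub.loc[sub["treatment"] == "INO", "c_r_star_nf"]
        if len(con) < 2 or len(ino) < 2:
            continue
        res = compare_treatments(con, ino)
        rows.append(
            {
                "das": int(das),
                "mean_con": float(con.mean()),
                "mean_ino": float(ino.mean()),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "test_used": res.test_used.value,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)
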