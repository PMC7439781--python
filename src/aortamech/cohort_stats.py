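"""Two-group inference protocol for cohort metrics.

The cohort is split evenly into a *nondilated* and a *dilated* group by the
aortic-diameter Z score.  For each metric the protocol runs Shapiro-Wilk
normality per group, Levene's variance-equality test (median-centered, i.e.
Brown-Forsythe), and then a two-sided two-sample t-test — pooled-variance
Student when Levene's p exceeds alpha, Welch otherwise.  Following the
reference protocol the normality result is recorded but does not gate the
t-test; a strict mode that falls back to a Mann-Whitney U test is available.

The packaged reference data (a 20-patient cohort table and the per-patient
simulated velocity / displacement / stress metrics) are exposed through
``load_reference_cohort`` / ``load_reference_metrics``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "PatientRecord",
    "GroupComparison",
    "load_reference_cohort",
    "load_reference_metrics",
    "split_by_zscore",
    "summarize",
    "normality_p",
    "variance_equality_p",
    "compare_groups",
    "compare_sex",
    "build_results_tables",
    "render_table_text",
]

GROUPS = ("nondilated", "dilated")


@dataclass(frozen=True)
class PatientRecord:
    """Demographic and hemodynamic fields of one patient."""

    id: str
    age: float          # years
    sex: str            # 'M' | 'F'
    height: float       # cm
    weight: float       # kg
    sbp: float          # mmHg
    dbp: float          # mmHg
    aad: float          # ascending aortic diameter, mm
    aad_z_score: float
    viscosity: float    # cPoise
    group: str | None = None

    def __post_init__(self):
        if self.sbp <= self.dbp:
            raise ValueError(f"{self.id}: SBP must exceed DBP")
        if self.aad <= 0:
            raise ValueError(f"{self.id}: AAD must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.id}: sex must be 'M' or 'F'")


def _read_packaged(name: str) -> pd.DataFrame:
    data = importlib.resources.files("aortamech.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(data))


def load_reference_cohort() -> pd.DataFrame:
    """Packaged 20-patient cohort table (demographics, pressures, AAD,
    Z scores, viscosity, group)."""
    return _read_packaged("reference_cohort.csv")


def load_reference_metrics() -> pd.DataFrame:
    """Packaged per-patient simulated metrics in long form
    (metric, phase, units, group, value); values are sorted within group."""
    return _read_packaged("reference_metrics.csv")


def reference_patient_records() -> list:
    """The packaged cohort as PatientRecord objects."""
    return [
        PatientRecord(
            id=r.patient_id, age=r.age_years, sex=r.sex, height=r.height_cm,
            weight=r.weight_kg, sbp=r.sbp_mmhg, dbp=r.dbp_mmhg, aad=r.aad_mm,
            aad_z_score=r.aad_z_score, viscosity=r.viscosity_cp, group=r.group,
        )
        for r in load_reference_cohort().itertuples()
    ]


def split_by_zscore(cohort: list) -> list:
    """Label an even-sized cohort by Z-score rank: lower half nondilated,
    upper half dilated.  Ties are broken by patient id (lexicographic), so
    the split is invariant to input order."""
    if len(cohort) % 2 != 0:
        raise ConfigurationError("cohort size must be even for the Z-score split")
    ranked = sorted(cohort, key=lambda r: (r.aad_z_score, r.id))
    half = len(cohort) // 2
    labeled = {r.id: ("nondilated" if i < half else "dilated")
               for i, r in enumerate(ranked)}
    return [replace(r, group=labeled[r.id]) for r in cohort]


def summarize(values) -> tuple:
    """(arithmetic mean, sample SD with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateDataError("need at least 2 values for mean +/- SD")
    return float(v.mean()), float(v.std(ddof=1))


def normality_p(values) -> float:
    """Shapiro-Wilk p-value (Royston's algorithm via scipy)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise DegenerateDataError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.allclose(v, v[0]):
        raise DegenerateDataError("constant sample: normality test undefined")
    return float(stats.shapiro(v).pvalue)


def variance_equality_p(values_a, values_b, center: str = "median") -> float:
    """Levene's test p-value; the default median centering is the
    Brown-Forsythe variant."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least 2 values")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        raise DegenerateDataError("both samples constant: variance test undefined")
    return float(stats.levene(a, b, center=center).pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """Full record of one two-group comparison."""

    metric: str
    shapiro_p: tuple          # per group, order GROUPS
    levene_p: float
    test_used: str            # 'student' | 'welch' | 'nonparametric'
    t_statistic: float
    p_value: float
    group_means: tuple
    group_sds: tuple
    n: tuple
    alpha: float = 0.05


def compare_groups(values_a, values_b, alpha: float = 0.05,
                   strict_normality: bool = False,
                   metric: str = "") -> GroupComparison:
    """Levene-gated two-sample comparison of two metric groups.

    Pooled-variance Student's t when Levene's p > alpha, Welch otherwise.
    With ``strict_normality`` a Shapiro-Wilk p below alpha in either group
    switches to a two-sided Mann-Whitney U test; by default normality is
    recorded but does not gate (matching the reference protocol).
    """
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    # Shapiro-Wilk needs n >= 3; smaller groups get NaN (recorded, not gating)
    sw = tuple(normality_p(v) if v.size >= 3 else float("nan") for v in (a, b))
    lev = variance_equality_p(a, b)
    if strict_normality and min(sw) < alpha:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test, tstat, p = "nonparametric", float(res.statistic), float(res.pvalue)
    elif lev > alpha:
        res = stats.ttest_ind(a, b)
        test, tstat, p = "student", float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        test, tstat, p = "welch", float(res.statistic), float(res.pvalue)
    (ma, sa), (mb, sb) = summarize(a), summarize(b)
    return GroupComparison(metric, sw, lev, test, tstat, p,
                           (ma, mb), (sa, sb), (a.size, b.size), alpha)


def compare_sex(sexes_a, sexes_b) -> float:
    """Two-sided Fisher exact p-value for the M/F composition of two groups
    (the protocol's nonparametric test for the categorical variable)."""
    table = [[sum(1 for s in g if s == "M"), sum(1 for s in g if s == "F")]
             for g in (sexes_a, sexes_b)]
    return float(stats.fisher_exact(table).pvalue)


def build_results_tables(metrics: pd.DataFrame, alpha: float = 0.05,
                         strict_normality: bool = False):
    """Render per-metric group tables in the reference layout.

    ``metrics`` is long-form (metric, phase, group, value).  Each
    (metric, phase) becomes a table with within-group ascending values and
    appended Mean +/- SD, Shapiro-Wilk, Levene and p-value rows.  Returns
    (tables: dict[(metric, phase)] -> DataFrame,
    comparisons: dict[(metric, phase)] -> GroupComparison,
    completeness: list of (metric, phase, missing group) entries).
    """
    tables, comparisons, incomplete = {}, {}, []
    for (metric, phase), sub in metrics.groupby(["metric", "phase"], sort=True):
        groups = {g: np.sort(sub.loc[sub.group == g, "value"].to_numpy())
                  for g in GROUPS}
        missing = [g for g in GROUPS if groups[g].size < 2]
        if missing:
            incomplete.extend((metric, phase, g) for g in missing)
            continue
        comp = compare_groups(groups["nondilated"], groups["dilated"],
                              alpha=alpha, strict_normality=strict_normality,
                              metric=f"{metric} ({phase})")
        n = max(g.size for g in groups.values())
        cols = {}
        for g in GROUPS:
            col = [f"{v:.6g}" for v in groups[g]] + [""] * (n - groups[g].size)
            cols[g] = col
        df = pd.DataFrame(cols)
        summary = pd.DataFrame(
            {
                "nondilated": [
                    f"{comp.group_means[0]:.2f} ± {comp.group_sds[0]:.2f}",
                    f"{comp.shapiro_p[0]:.2f}",
                    f"{comp.levene_p:.2f}",
                    f"{comp.p_value:.3f}",
                ],
                "dilated": [
                    f"{comp.group_means[1]:.2f} ± {comp.group_sds[1]:.2f}",
                    f"{comp.shapiro_p[1]:.2f}", "", "",
                ],
            },
            index=["Mean ± SD", "Shapiro-Wilk", "Levene", "p value"],
        )
        df.index = [str(i + 1) for i in range(n)]
        tables[(metric, phase)] = pd.concat([df, summary])
        comparisons[(metric, phase)] = comp
    return tables, comparisons, incomplete


def render_table_text(tables: dict) -> str:
    """Aligned plain-text rendering of the result tables."""
    chunks = []
    for (metric, phase), df in sorted(tables.items()):
        chunks.append(f"== {metric} [{phase}] ==")
        chunks.append(df.to_string())
        chunks.append("")
    return "\n".join(chunks)
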