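"""Between-group baseline statistics for the cohort covariate table.

Routes each covariate to the appropriate two-group test: pooled-variance
t-test for normally distributed continuous variables, Mann-Whitney U for
non-normal ones, and Pearson chi-square (no continuity correction) for
categorical ones, reproducing the conventions of a clinical baseline
characteristics table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import CohortRecord, GOOD, POOR

__all__ = [
    "GroupSummary",
    "TestResult",
    "ttest_pooled",
    "chi_square",
    "mann_whitney",
    "kruskal_wallis",
    "anova_oneway",
    "table1_report",
    "load_reference_table",
    "reference_table_pvalues",
]


@dataclass(frozen=True)
class GroupSummary:
    """n with either mean/sd (normal), median/iqr (non-normal) or
    category counts."""

    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    iqr: float | None = None
    counts: dict | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group must be non-empty")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p value must lie in [0, 1]")


def _summary_args(group):
    """Accept raw values or an (n, mean, sd) GroupSummary."""
    if isinstance(group, GroupSummary):
        if group.mean is None or group.sd is None:
            raise ValueError("summary input needs n, mean and sd")
        return group.n, group.mean, group.sd
    vals = np.asarray(group, dtype=float)
    if len(vals) < 2:
        raise ValueError("each group needs n >= 2")
    return len(vals), float(vals.mean()), float(vals.std(ddof=1))


def ttest_pooled(a, b) -> TestResult:
    """Two-sided two-independent-samples t-test with pooled variance,
    computable from raw values or (n, mean, sd) summaries."""
    n1, m1, s1 = _summary_args(a)
    n2, m2, s2 = _summary_args(b)
    if s1 == 0 and s2 == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult("pooled t", float(res.statistic), float(res.pvalue), df=n1 + n2 - 2)


def chi_square(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, without
    continuity correction, df = (r-1)(c-1)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = sps.chi2_contingency(tab, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("expected counts must be positive")
    return TestResult("chi-square", float(res.statistic), float(res.pvalue), df=res.dof)


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free
    samples (both n <= 20), otherwise the tie-corrected normal
    approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(f"mann-whitney ({method})", float(res.statistic), float(res.pvalue))


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square reference,
    df = k - 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        raise ValueError("all values identical: H undefined")
    res = sps.kruskal(*groups)
    return TestResult("kruskal-wallis", float(res.statistic), float(res.pvalue),
                      df=len(groups) - 1)


def anova_oneway(*groups) -> TestResult:
    """One-way ANOVA F test, df = (k-1, N-k)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups, each with n >= 2")
    res = sps.f_oneway(*groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    return TestResult("one-way anova", float(res.statistic), float(res.pvalue),
                      df=(k - 1, n_total - k))


# ---------------------------------------------------------------------------
# cohort table report
# ---------------------------------------------------------------------------

_CONTINUOUS = ("age", "nihss", "grade")
_CATEGORICAL = (
    "sex", "onset_bin", "artery", "toast", "treatment", "hemorrhagic_transformation",
)


def _is_normal(*groups, alpha=0.05) -> bool:
    """Shapiro-Wilk normality gate applied per group."""
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 3 or np.all(g == g[0]):
            return False
        if sps.shapiro(g).pvalue < alpha:
            return False
    return True


def _continuous_row(name, a, b, normal_alpha):
    if _is_normal(a, b, alpha=normal_alpha):
        result = ttest_pooled(a, b)
        summaries = [
            GroupSummary(n=len(g), mean=float(np.mean(g)), sd=float(np.std(g, ddof=1)))
            for g in (a, b)
        ]
    else:
        result = mann_whitney(a, b)
        summaries = [
            GroupSummary(
                n=len(g),
                median=float(np.median(g)),
                iqr=float(np.percentile(g, 75) - np.percentile(g, 25)),
            )
            for g in (a, b)
        ]
    return summaries, result


def table1_report(records: list[CohortRecord], normal_alpha: float = 0.05) -> pd.DataFrame:
    """Build a baseline-characteristics comparison of the poor vs good
    collateral groups: one row per covariate with group summaries, the
    routed test, its statistic and p value."""
    df = pd.DataFrame([vars(r) for r in records])
    labels = set(df["label"])
    if labels != {GOOD, POOR}:
        raise ValueError("cohort must contain both good and poor labels")
    poor = df[df["label"] == POOR]
    good = df[df["label"] == GOOD]
    rows = []
    for var in _CONTINUOUS:
        if var not in df:
            continue
        (s_poor, s_good), result = _continuous_row(
            var, poor[var].to_numpy(float), good[var].to_numpy(float), normal_alpha
        )
        rows.append(_row(var, s_poor, s_good, result))
    for var in _CATEGORICAL:
        if var not in df:
            continue
        tab = pd.crosstab(df["label"], df[var]).reindex([POOR, GOOD])
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        if tab.shape[1] < 2:
            continue  # single observed category: no comparison possible
        result = chi_square(tab.to_numpy())
        s_poor = GroupSummary(n=len(poor), counts=tab.loc[POOR].to_dict())
        s_good = GroupSummary(n=len(good), counts=tab.loc[GOOD].to_dict())
        rows.append(_row(var, s_poor, s_good, result))
    return pd.DataFrame(rows)


def _fmt(s: GroupSummary) -> str:
    if s.counts is not None:
        return "; ".join(f"{k}: {v}" for k, v in s.counts.items())
    if s.mean is not None:
        return f"{s.mean:.2f} +/- {s.sd:.2f}"
    return f"{s.median:.2f} ({s.iqr:.2f})"


def _row(var, s_poor, s_good, result: TestResult) -> dict:
    return {
        "variable": var,
        "poor": _fmt(s_poor),
        "good": _fmt(s_good),
        "test": result.test,
        "statistic": result.statistic,
        "p_value": result.p_value,
    }


# ---------------------------------------------------------------------------
# reference cohort fixture
# ---------------------------------------------------------------------------

def load_reference_table() -> dict:
    """The bundled baseline table of the 92-patient reference stroke
    cohort (group counts and summary statistics)."""
    path = resources.files("collateral4d.data") / "reference_cohort.json"
    return json.loads(path.read_text())


def reference_table_pvalues() -> dict:
    """Recompute the between-group p values from the reference table's
    printed counts and summaries: pooled t for age, uncorrected Pearson
    chi-square for the categorical rows."""
    ref = load_reference_table()
    age = ref["age"]
    out = {
        "age": ttest_pooled(
            GroupSummary(**age["poor"]), GroupSummary(**age["good"])
        ).p_value
    }
    for var in ("gender", "onset", "treatment", "hemorrhage", "artery", "toast"):
        out[var] = chi_square([ref[var]["poor"], ref[var]["good"]]).p_value
    return out
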