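"""Group statistics, agreement, risk scoring, and report tables.

Continuous two-group comparisons route to the independent-samples t-test
(Welch by default) when both groups pass a Shapiro-Wilk normality check at
alpha = 0.05, and to the Mann-Whitney U test otherwise; categorical counts
use Fisher's exact test (two-sided by probability summation); paired LA vs
LAA contrasts use the paired t-test; associations use Spearman rank
correlation; inter-observer agreement uses the two-way random-effects,
absolute-agreement, single-measure ICC, i.e. ICC(2,1).  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "AgreementResult",
    "RiskScore",
    "compare_continuous",
    "fisher_exact",
    "spearman",
    "paired_t",
    "icc_absolute_agreement",
    "cha2ds2_vasc",
    "build_report",
]

NORMALITY_ALPHA = 0.05


@dataclass
class GroupComparison:
    variable: str
    summary_a: str
    summary_b: str
    test: str  # one of {"t", "mann_whitney", "fisher", "paired_t"}
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class AgreementResult:
    icc: float
    ci95: tuple[float, float]
    model: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.icc <= hi):
            raise ValueError("ICC estimate outside its confidence interval")


@dataclass
class RiskScore:
    """CHA2DS2-VASc components; ``points`` sums the standard weights
    (age >= 75 and prior stroke/TIA score 2, the rest 1)."""

    chf_lv_dysfunction: bool = False
    hypertension: bool = False
    age_75_or_over: bool = False
    diabetes: bool = False
    stroke_tia: bool = False
    vascular_disease: bool = False
    age_65_to_74: bool = False
    female: bool = False

    @property
    def points(self) -> int:
        if self.age_75_or_over and self.age_65_to_74:
            raise ValueError("mutually exclusive age categories both set")
        return (
            int(self.chf_lv_dysfunction)
            + int(self.hypertension)
            + 2 * int(self.age_75_or_over)
            + int(self.diabetes)
            + 2 * int(self.stroke_tia)
            + int(self.vascular_disease)
            + int(self.age_65_to_74)
            + int(self.female)
        )


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.2f} [{q1:.2f}-{q3:.2f}]"


def _is_normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > NORMALITY_ALPHA


def compare_continuous(a: Sequence[float], b: Sequence[float],
                       method: str = "auto", welch: bool = True,
                       variable: str = "") -> GroupComparison:
    """Two-group comparison of a continuous variable.

    ``auto`` picks the t-test when both samples pass Shapiro-Wilk at
    alpha = 0.05, else Mann-Whitney U; both tests are two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if method == "auto":
        method = "t" if (_is_normal(a) and _is_normal(b)) else "mann_whitney"
    if method == "t":
        res = sps.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison(variable, _mean_sd(a), _mean_sd(b), "t",
                               float(res.statistic), float(res.pvalue))
    if method == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(variable, _median_iqr(a), _median_iqr(b),
                               "mann_whitney", float(res.statistic),
                               float(res.pvalue))
    raise ValueError(f"unknown method {method!r}")


def fisher_exact(table: Sequence[Sequence[int]], variable: str = "") -> GroupComparison:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p-value sums hypergeometric probabilities of all tables at
    most as probable as the observed one (probability-summation rule).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    res = sps.fisher_exact(t, alternative="two-sided")
    n_a, n_b = t.sum(axis=1)
    summary_a = f"{t[0, 0]}/{n_a}"
    summary_b = f"{t[1, 0]}/{n_b}"
    return GroupComparison(variable, summary_a, summary_b, "fisher",
                           float(res[0]), float(res[1]))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(before: Sequence[float], after: Sequence[float],
             variable: str = "") -> GroupComparison:
    """Two-sided paired t-test on the per-subject differences."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = b - a
    if np.all(d == 0):
        return GroupComparison(variable, _mean_sd(a), _mean_sd(b), "paired_t",
                               0.0, 1.0)
    if np.std(d, ddof=1) == 0:
        # constant nonzero shift: the t statistic diverges
        return GroupComparison(variable, _mean_sd(a), _mean_sd(b), "paired_t",
                               float(np.sign(d.mean()) * np.inf), 0.0)
    res = sps.ttest_rel(b, a)
    return GroupComparison(variable, _mean_sd(a), _mean_sd(b), "paired_t",
                           float(res.statistic), float(res.pvalue))


def icc_absolute_agreement(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` has shape (subjects, 2) for two raters; the 95% CI is the
    F-based interval.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must have shape (subjects, 2)")
    if ratings.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("missing or non-finite ratings")
    import pingouin as pg

    n = ratings.shape[0]
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["A", "B"], n),
            "score": ratings.reshape(-1),
        }
    )
    icc = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                             ratings="score")
    sel = icc[icc["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    est = float(row["ICC"])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        # degenerate zero-residual case (e.g. identical raters)
        lo, hi = est, est
    est = float(np.clip(est, lo, hi))
    return AgreementResult(icc=est, ci95=(lo, hi),
                           model="two-way random, absolute agreement, single measures")


def cha2ds2_vasc(flags: RiskScore) -> int:
    """Total CHA2DS2-VASc points (0-9)."""
    return flags.points


def build_report(metrics: pd.DataFrame, group_col: str = "group",
                 compare: Optional[tuple[str, str]] = None) -> pd.DataFrame:
    """Per-variable group summary table with two-group test p-values.

    ``metrics`` holds one row per subject with a group label column and
    numeric metric columns.  With two groups (or an explicit ``compare``
    pair) each variable gets the auto-selected two-sided test; with one
    group, summaries only.
    """
    if group_col not in metrics.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = list(pd.unique(metrics[group_col]))
    if any(metrics[metrics[group_col] == g].empty for g in groups) or not groups:
        raise ValueError("every group must be non-empty")
    if compare is None and len(groups) == 2:
        compare = (groups[0], groups[1])
    rows = []
    variables = [c for c in metrics.columns
                 if c != group_col and pd.api.types.is_numeric_dtype(metrics[c])]
    for var in variables:
        row: dict = {"variable": var}
        for g in groups:
            x = metrics.loc[metrics[group_col] == g, var].dropna().to_numpy()
            row[f"{g}_summary"] = _mean_sd(x) if _is_normal(x) else _median_iqr(x)
            row[f"{g}_mean"] = float(np.mean(x))
        if compare is not None:
            a = metrics.loc[metrics[group_col] == compare[0], var].dropna()
            b = metrics.loc[metrics[group_col] == compare[1], var].dropna()
            cmp_res = compare_continuous(a, b, variable=var)
            row["test"] = cmp_res.test
            row["p_value"] = cmp_res.p_value
        rows.append(row)
    return pd.DataFrame(rows)
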