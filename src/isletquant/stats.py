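"""Normality-gated two-group comparisons and summaries.

Comparisons follow the convention of the source assay's statistics: both
samples are checked for normality (Shapiro-Wilk, per-group, alpha = 0.05);
if both pass, an unpaired two-sided Welch t-test is run and groups are
summarised as mean ± 95% CI (t-quantile × SEM); otherwise a two-sided
Mann-Whitney U test is run and groups are summarised as median (IQR).
Significance is declared at p < 0.05.  No multiple-testing correction is
applied.  A glycemia classifier applies the 13.3 mmol/l diagnostic cut-off
for diabetes (values below the cut-off are non-diabetic; the boundary itself
is taken as diabetic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "ComparisonResult",
    "normality_gate",
    "compare_groups",
    "summarize",
    "classify_glycemia",
    "GLYCEMIA_CUTOFF_MMOL_L",
]

GLYCEMIA_CUTOFF_MMOL_L = 13.3
NORMALITY_ALPHA = 0.05
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    groups: tuple[str, str]
    test_used: str  # "unpaired-t" | "mann-whitney"
    statistic: float
    p_value: float
    n: tuple[int, int]
    summary_a: dict[str, float]
    summary_b: dict[str, float]
    significant: bool


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro undefined, treat as non-normal
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(x).pvalue > alpha)


def normality_gate(
    sample_a: np.ndarray, sample_b: np.ndarray, alpha: float = NORMALITY_ALPHA
) -> str:
    """Choose the test: ``unpaired-t`` if both groups pass Shapiro-Wilk at
    ``alpha``, else ``mann-whitney``."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("normality gate requires n >= 3 per group")
    both_normal = _shapiro_normal(a, alpha) and _shapiro_normal(b, alpha)
    return "unpaired-t" if both_normal else "mann-whitney"


def summarize(sample: np.ndarray, style: str = "mean_ci") -> dict[str, float]:
    """Summarise one sample.

    styles: ``mean_ci`` (mean, 95% CI bounds via the t-quantile with n-1 df),
    ``mean_sem`` (mean, SEM), ``median_iqr`` (median, Q1, Q3).
    """
    x = np.asarray(sample, float)
    n = len(x)
    if n < 2:
        raise DataError("summaries require n >= 2")
    if style == "mean_ci":
        sem = x.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.975, n - 1) * sem
        m = x.mean()
        return {"mean": m, "ci95_low": m - half, "ci95_high": m + half, "n": n}
    if style == "mean_sem":
        return {"mean": x.mean(), "sem": x.std(ddof=1) / np.sqrt(n), "n": n}
    if style == "median_iqr":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": med, "q1": q1, "q3": q3, "n": n}
    raise DataError(f"unknown summary style {style!r}")


def compare_groups(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    metric: str = "",
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-group comparison with the normality gate.

    Normal path: two-sided Welch (unequal-variance) t-test, mean ± 95% CI
    summaries.  Non-normal path: two-sided Mann-Whitney U, median (IQR)
    summaries.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    test = normality_gate(a, b)
    if test == "unpaired-t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        sa, sb = summarize(a, "mean_ci"), summarize(b, "mean_ci")
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        sa, sb = summarize(a, "median_iqr"), summarize(b, "median_iqr")
    return ComparisonResult(
        metric=metric,
        groups=groups,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        n=(len(a), len(b)),
        summary_a=sa,
        summary_b=sb,
        significant=bool(p < SIGNIFICANCE_ALPHA),
    )


def classify_glycemia(glucose_mmol_l: float) -> str:
    """Diabetes classification from endpoint blood glucose.

    Values below 13.3 mmol/l are non-diabetic; the cut-off itself counts as
    diabetic.
    """
    if glucose_mmol_l < 0:
        raise DataError("blood glucose cannot be negative")
    return "diabetic" if glucose_mmol_l >= GLYCEMIA_CUTOFF_MMOL_L else "non-diabetic"
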