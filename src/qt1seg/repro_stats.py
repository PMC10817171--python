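"""Rater-agreement statistics battery.

Per-subject coefficient of variation and pairwise error, average-measures
ICC with a 95% CI (two-way random effects, absolute agreement — the SPSS
"two-way random" model), Bland-Altman analysis with proportional-bias
testing, Wilcoxon signed-rank and paired t comparisons.

Conventions: sample SDs (n-1) throughout; differences are oriented
first-column minus second-column (observer1 - observer2, first - second).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from qt1seg.exceptions import ValidationError
from qt1seg.imaging_io import MeasurementTable

logger = logging.getLogger(__name__)

LOA_WIDTH = 1.96
ALPHA = 0.05


def pair_error(a: float, b: float) -> float:
    """Pairwise error in %: |a - b| / pair mean x 100."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("pair_error requires strictly positive values")
    return np.abs(a - b) / ((a + b) / 2.0) * 100.0


def pair_cov(a: float, b: float) -> float:
    """Coefficient of variation of a pair in %: sample SD / mean x 100.

    For two values this equals ``pair_error / sqrt(2)`` identically.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("pair_cov requires strictly positive values")
    sd = np.abs(a - b) / np.sqrt(2.0)  # sample SD of {a, b}
    return sd / ((a + b) / 2.0) * 100.0


def _mean_squares(x: np.ndarray) -> Tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, cols=raters)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    # np.float64 so degenerate tables (MSE = 0) yield inf/nan CIs, not raises
    msr = np.float64(ss_rows / (n - 1))
    msc = np.float64(ss_cols / (k - 1))
    mse = np.float64(ss_err / ((n - 1) * (k - 1)))
    return msr, msc, mse


def icc_average(
    table: MeasurementTable, model: str = "icc2k", alpha: float = ALPHA
) -> Tuple[float, float, float]:
    """Average-measures ICC with its 95% CI.

    Default model ``"icc2k"`` is two-way random effects, absolute
    agreement, average measures (McGraw & Wong ICC(A,k); SPSS "two-way
    random, absolute agreement, average measures"):

        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

    with the CI obtained from the single-measures ICC(A,1) F bounds
    (Satterthwaite degrees of freedom) stepped up by the Spearman-Brown
    relation.  ``"icc3k"`` (two-way mixed, consistency) is available
    behind the flag.

    Returns ``(icc, ci_low, ci_high)``.
    """
    x = table.values
    n, k = x.shape
    if n < 3:
        raise ValidationError("ICC requires at least 3 subjects")
    msr, msc, mse = _mean_squares(x)
    if msr <= mse:
        warnings.warn(
            "between-subject variance does not exceed error variance; "
            "ICC is degenerate but reported as computed",
            stacklevel=2,
        )

    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    fq_u = stats.f.ppf(1 - alpha / 2, df1, df2)
    fq_l = stats.f.ppf(1 - alpha / 2, df2, df1)

    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "icc3k":
            icc = (msr - mse) / msr
            f_obs = msr / mse
            lo = 1.0 - 1.0 / (f_obs / fq_u)
            hi = 1.0 - 1.0 / (f_obs * fq_l)
            return float(icc), float(lo), float(hi)
        if model != "icc2k":
            raise ValidationError(f"unknown ICC model {model!r}")

        icc_k = (msr - mse) / (msr + (msc - mse) / n)
        icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

        # Satterthwaite df for the ICC(A,1) interval (McGraw & Wong 1996)
        fj = msc / mse
        vn = df2 * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        vd = df1 * k**2 * icc_1**2 * fj**2 + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, df1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, df1)
        l1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        u1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        lo = l1 * k / (1 + l1 * (k - 1))
        hi = u1 * k / (1 + u1 * (k - 1))
    return float(icc_k), float(lo), float(hi)


def bland_altman(table: MeasurementTable) -> Dict[str, Optional[float]]:
    """Bland-Altman bias, limits of agreement and proportional bias.

    Differences ``d = col1 - col2``; means ``m = (col1 + col2)/2``.
    ``bias = mean(d)``; ``loa = bias +/- 1.96 * SD(d)`` (sample SD);
    proportional bias is the Pearson correlation of d against m with its
    two-sided t-test p-value.  When the differences are constant the
    correlation is undefined and reported as ``None`` with a warning.
    """
    if table.n < 3:
        raise ValidationError("Bland-Altman requires at least 3 subjects")
    d = table.col(0) - table.col(1)
    m = (table.col(0) + table.col(1)) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - LOA_WIDTH * sd
    loa_high = bias + LOA_WIDTH * sd
    if np.allclose(d, d[0]) or np.allclose(m, m[0]):
        warnings.warn(
            "constant differences or means; proportional bias undefined",
            stacklevel=2,
        )
        r_prop = p_prop = None
    else:
        res = stats.pearsonr(d, m)
        r_prop, p_prop = float(res.statistic), float(res.pvalue)
    return {
        "bias": bias,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "r_prop": r_prop,
        "p_prop": p_prop,
    }


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon convention).  The exact
    distribution is used for n <= 25 without ties; otherwise the normal
    approximation with continuity correction.  All-zero differences give
    p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; Wilcoxon p set to 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        raise ValidationError(
            f"need >= 5 non-zero differences for the Wilcoxon test, got {d.size}"
        )
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def paired_t(a, b) -> float:
    """Two-sided paired t-test p-value; identical samples give p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b):
        return 1.0
    res = stats.ttest_rel(a, b)
    return float(res.pvalue)


@dataclass
class AgreementReport:
    """Full agreement battery for one two-column measurement table."""

    cov: np.ndarray  # per-subject CoV, %
    error: np.ndarray  # per-subject pairwise error, %
    mean_cov: float
    mean_error: float
    icc: Tuple[float, float, float]  # (point, ci_low, ci_high)
    bland_altman: Dict[str, Optional[float]]
    n: int
    labels: Tuple[str, str]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "labels": list(self.labels),
            "per_subject_cov_pct": self.cov.tolist(),
            "per_subject_error_pct": self.error.tolist(),
            "mean_cov_pct": self.mean_cov,
            "mean_error_pct": self.mean_error,
            "icc": {
                "value": self.icc[0],
                "ci_low": self.icc[1],
                "ci_high": self.icc[2],
            },
            "bland_altman": self.bland_altman,
        }


def agreement_report(table: MeasurementTable, icc_model: str = "icc2k") -> AgreementReport:
    """Compute the full agreement battery for one table."""
    a, b = table.col(0), table.col(1)
    cov = pair_cov(a, b)
    error = pair_error(a, b)
    return AgreementReport(
        cov=cov,
        error=error,
        mean_cov=float(cov.mean()),
        mean_error=float(error.mean()),
        icc=icc_average(table, model=icc_model),
        bland_altman=bland_altman(table),
        n=table.n,
        labels=table.labels,
    )


@dataclass
class MethodComparison:
    """Agreement of two ROI-placement methods plus paired comparisons."""

    method_a: AgreementReport
    method_b: AgreementReport
    p_cov_wilcoxon: float
    p_error_wilcoxon: float
    p_cov_ttest: float
    p_error_ttest: float

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a.to_dict(),
            "method_b": self.method_b.to_dict(),
            "p_cov_wilcoxon": self.p_cov_wilcoxon,
            "p_error_wilcoxon": self.p_error_wilcoxon,
            "p_cov_ttest": self.p_cov_ttest,
            "p_error_ttest": self.p_error_ttest,
        }


def compare_methods(
    table_a: MeasurementTable, table_b: MeasurementTable
) -> MethodComparison:
    """Compare two methods' per-subject CoV and error on the same subjects.

    Wilcoxon signed-rank and paired t p-values are computed on the paired
    per-subject CoV and error values (method A vs method B).
    """
    if table_a.n != table_b.n or list(table_a.subjects) != list(table_b.subjects):
        raise ValidationError("the two tables must cover the same subjects")
    rep_a = agreement_report(table_a)
    rep_b = agreement_report(table_b)
    return MethodComparison(
        method_a=rep_a,
        method_b=rep_b,
        p_cov_wilcoxon=wilcoxon_signed_rank(rep_a.cov, rep_b.cov),
        p_error_wilcoxon=wilcoxon_signed_rank(rep_a.error, rep_b.error),
        p_cov_ttest=paired_t(rep_a.cov, rep_b.cov),
        p_error_ttest=paired_t(rep_a.error, rep_b.error),
    )
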