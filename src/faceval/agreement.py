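"""Method-error statistics: paired t, ICC(A,k), Bland-Altman, sample size.

The ICC is the two-way random-effects, absolute-agreement,
average-measures coefficient (McGraw & Wong's ICC(A,k)), with the
F-based confidence interval.  Sample size for a paired design uses exact
noncentral-t power, iterated upward until the target power is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PairedTResult", "IccResult", "BlandAltmanReport", "PairedDesignSpec",
    "paired_t", "icc_a_k", "bland_altman", "paired_sample_size",
    "paired_power",
]


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float
    sd_difference: float
    degenerate: bool = False


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float
    sd: float
    bias_ci: tuple
    lower_limit: float
    upper_limit: float
    lower_limit_ci: tuple
    upper_limit_ci: tuple
    n: int


@dataclass(frozen=True)
class PairedDesignSpec:
    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.delta <= 0 or self.sd <= 0:
            raise ValidationError("delta and sd must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValidationError("alpha and power must be in (0, 1)")


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t test on d = x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean != 0.0:
            raise ValidationError(
                "differences have zero variance but nonzero mean")
        return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_difference=0.0,
                             sd_difference=0.0, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, mean_difference=mean,
                         sd_difference=sd)


def _anova_two_way(m: np.ndarray):
    """Mean squares of the two-way crossed single-score decomposition."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a_k(matrix, alpha: float = 0.05) -> IccResult:
    """ICC(A,k): two-way random effects, absolute agreement, average measures.

    Point estimate (MSR - MSE) / (MSR + (MSC - MSE)/n); the CI is the
    McGraw-Wong F-based interval for ICC(A,1) with Satterthwaite degrees
    of freedom, stepped up to average measures.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("ratings matrix must be >= 2 subjects x 2 raters")
    if not np.isfinite(m).all():
        raise ValidationError("ratings matrix has missing/non-finite cells")
    n, k = m.shape
    msr, msc, mse = _anova_two_way(m)
    if msr == 0.0 and mse == 0.0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, degenerate=True)

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    # single-measures estimate feeds the Satterthwaite df of the CI
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc_1 >= 1.0 - 1e-15:  # perfect agreement; F interval collapses
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0, degenerate=True)

    a = k * icc_1 / (n * (1.0 - icc_1))
    b = 1.0 + k * icc_1 * (n - 1) / (n * (1.0 - icc_1))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1)
            + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo1 = (n * (msr - f_low * mse)
           / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi1 = (n * (f_up * msr - mse)
           / (k * msc + (k * n - k - n) * mse + n * f_up * msr))

    def step_up(r1):
        return k * r1 / (1.0 + (k - 1) * r1)

    return IccResult(icc=float(icc_k), ci_low=float(step_up(lo1)),
                     ci_high=float(step_up(hi1)))


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanReport:
    """Bias, 1.96-SD limits of agreement, and t-based CIs for bias and limits."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValidationError("Bland-Altman needs at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_limit = tq * sd * np.sqrt(3.0 / n)
    lower = bias - 1.96 * sd
    upper = bias + 1.96 * sd
    return BlandAltmanReport(
        bias=bias, sd=sd,
        bias_ci=(bias - half_bias, bias + half_bias),
        lower_limit=lower, upper_limit=upper,
        lower_limit_ci=(lower - half_limit, lower + half_limit),
        upper_limit_ci=(upper - half_limit, upper + half_limit),
        n=n,
    )


def paired_power(n: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided paired t test at sample size ``n``."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = delta / sd * np.sqrt(n)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(crit, df, nc)
                 + stats.nct.cdf(-crit, df, nc))


def paired_sample_size(spec: PairedDesignSpec, n_max: int = 100000) -> int:
    """Smallest n >= 2 whose exact noncentral-t power reaches the target."""
    for n in range(2, n_max + 1):
        if paired_power(n, spec.delta, spec.sd, spec.alpha) >= spec.power:
            return n
    raise ValidationError("sample size exceeds n_max")
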