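"""Method-agreement statistics: two-way absolute-agreement ICC, Bland-Altman
limits, percentage error, and exceedance counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ICCResult",
    "AgreementReport",
    "icc_absolute",
    "bland_altman",
    "percentage_error",
    "exceedance_counts",
    "agreement_report",
]

DEFAULT_LIMIT = 5.0  # T-points; 0.5 reference-group SD units


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    f: float
    df1: float
    df2: float
    p: float


def icc_absolute(m1, m2, alpha: float = 0.05) -> ICCResult:
    """Single-measurement, absolute-agreement ICC under the two-way model
    (McGraw & Wong's A-1), from the standard mean-squares decomposition.

    F (and its p) tests MSR/MSE; the CI uses the A-1 closed form.
    """
    y = np.column_stack([np.asarray(m1, float), np.asarray(m2, float)])
    if np.isnan(y).any():
        raise ValueError("missing values not allowed")
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least three paired measurements")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    icc = (msr - mse) / denom

    f = msr / mse if mse > 0 else np.inf
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0

    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse > 0 and icc < 1.0:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    else:
        ci = (1.0, 1.0)
    return ICCResult(icc=float(icc), ci=ci, f=float(f), df1=df1, df2=df2, p=p)


def bland_altman(m1, m2) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of d = m1 - m2:
    (bias, bias - 1.96*SD(d), bias + 1.96*SD(d))."""
    d = np.asarray(m1, float) - np.asarray(m2, float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least two paired measurements")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def percentage_error(loa_low: float, loa_high: float, grand_mean: float) -> float:
    """100 * (limits-of-agreement width) / grand mean."""
    if grand_mean == 0:
        raise ValueError("grand mean must be non-zero")
    return float(100.0 * (loa_high - loa_low) / grand_mean)


def exceedance_counts(differences, limit: float = DEFAULT_LIMIT) -> dict:
    """Partition differences into D < -limit, -limit <= D <= limit (bounds
    inclusive), and D > limit; counts plus percentages of n."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    d = np.asarray(differences, float)
    d = d[~np.isnan(d)]
    n = d.size
    below = int((d < -limit).sum())
    above = int((d > limit).sum())
    within = n - below - above
    pct = lambda c: 100.0 * c / n if n else 0.0  # noqa: E731
    return {
        "n": n,
        "below": below,
        "within": within,
        "above": above,
        "pct_below": pct(below),
        "pct_within": pct(within),
        "pct_above": pct(above),
    }


@dataclass
class AgreementReport:
    """Full correspondence summary for (method, reference) paired T-scores."""

    icc: ICCResult
    bias: float
    loa_low: float
    loa_high: float
    perc_err: float
    counts: dict

    def to_dict(self) -> dict:
        return {
            "icc": self.icc.icc,
            "icc_ci_low": self.icc.ci[0],
            "icc_ci_high": self.icc.ci[1],
            "icc_f": self.icc.f,
            "icc_p": self.icc.p,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "perc_err": self.perc_err,
            **self.counts,
        }


def agreement_report(method, reference, limit: float = DEFAULT_LIMIT) -> AgreementReport:
    """Compare a candidate T-score method against a reference-standard one.

    Differences are method - reference; the percentage error divides the
    limits-of-agreement width by the grand mean of the reference method.
    """
    method = np.asarray(method, float)
    reference = np.asarray(reference, float)
    m = ~np.isnan(method) & ~np.isnan(reference)
    method, reference = method[m], reference[m]
    bias, lo, hi = bland_altman(method, reference)
    return AgreementReport(
        icc=icc_absolute(method, reference),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        perc_err=percentage_error(lo, hi, float(reference.mean())),
        counts=exceedance_counts(method - reference, limit),
    )
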