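"""Raw summed scores, descriptive statistics, reliability, group contrasts,
and mid-rank percentile ranks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ItemResponseMatrix

__all__ = [
    "DescriptiveStats",
    "GroupContrast",
    "sum_score",
    "sum_scores",
    "descriptives",
    "cronbach_alpha",
    "mcdonald_omega",
    "loadings_from_discriminations",
    "cohens_d_welch",
    "percentile_rank",
]

logger = logging.getLogger(__name__)

SHAPIRO_CAP = 4999  # largest n passed to the Shapiro-Wilk routine


@dataclass
class DescriptiveStats:
    """Summary moments of a numeric sample.

    ``skew``/``kurt`` are None when undefined (constant sample); ``kurt`` is
    excess kurtosis.  ``w`` is a Shapiro-Wilk statistic when computed.
    """

    n: int
    mean: float
    sd: float
    skew: float | None = None
    kurt: float | None = None
    w: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class GroupContrast:
    """Pooled-SD Cohen's d plus a Welch t-test from summary statistics."""

    d: float
    d_ci: tuple[float, float]
    t: float
    df: float
    p: float


def sum_score(responses, policy: str = "complete", max_imputed: int = 2) -> float | None:
    """Sum one respondent's item values.

    ``policy='complete'`` returns None (with a log entry) when any item is
    missing; ``policy='person_mean'`` imputes up to ``max_imputed`` missing
    items with the respondent's mean of the observed items.
    """
    if policy not in ("complete", "person_mean"):
        raise ValueError(f"unknown missing-item policy {policy!r}")
    x = np.asarray(responses, dtype=float)
    missing = np.isnan(x)
    if not missing.any():
        return float(x.sum())
    if policy == "complete":
        logger.info("respondent dropped: %d missing item(s) under complete-case policy",
                    int(missing.sum()))
        return None
    if policy == "person_mean":
        if missing.sum() > max_imputed:
            logger.info("respondent dropped: %d missing items exceeds imputation cap %d",
                        int(missing.sum()), max_imputed)
            return None
        return float(x[~missing].mean() * x.size)
    raise AssertionError("unreachable")


def sum_scores(matrix: ItemResponseMatrix, policy: str = "complete",
               max_imputed: int = 2) -> np.ndarray:
    """Per-respondent summed scores; None-scored respondents become NaN."""
    out = np.empty(matrix.n_respondents)
    for j in range(matrix.n_respondents):
        s = sum_score(matrix.responses[j], policy=policy, max_imputed=max_imputed)
        out[j] = np.nan if s is None else s
    return out


def descriptives(values, estimator: str = "moment", shapiro: bool = True,
                 seed: int = 0) -> DescriptiveStats:
    """Mean, sample SD (n-1), skewness, excess kurtosis and optional W.

    ``estimator='moment'`` uses the plain moment ratios g1 and g2;
    ``'adjusted'`` uses the bias-adjusted Fisher-Pearson variants.  Constant
    samples get ``skew=kurt=None`` rather than silent NaNs.  Shapiro-Wilk is
    delegated to scipy; above its validity cap a fixed-seed subsample is used.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n >= 2 else 0.0
    skew = kurt = w = None
    if n >= 3:
        if np.ptp(x) == 0:
            logger.info("constant sample: skewness/kurtosis undefined")
        else:
            bias = estimator == "moment"
            if estimator not in ("moment", "adjusted"):
                raise ValueError(f"unknown estimator {estimator!r}")
            skew = float(stats.skew(x, bias=bias))
            kurt = float(stats.kurtosis(x, bias=bias))
        if shapiro:
            xs = x
            if n > SHAPIRO_CAP:
                rng = np.random.default_rng(seed)
                xs = rng.choice(x, SHAPIRO_CAP, replace=False)
            if np.ptp(xs) > 0:
                w = float(stats.shapiro(xs).statistic)
    return DescriptiveStats(n=n, mean=mean, sd=sd, skew=skew, kurt=kurt, w=w)


def cronbach_alpha(matrix: ItemResponseMatrix) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances)/variance(total)).

    Computed on complete cases only.
    """
    X = matrix.responses
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete]
    if X.shape[0] < 2:
        raise ValueError("need at least two complete respondents")
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least two items")
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def loadings_from_discriminations(a) -> np.ndarray:
    """Standardized loadings implied by logistic-GRM slopes (scale constant
    1.0): lambda = a / sqrt(a^2 + pi^2/3)."""
    a = np.asarray(a, dtype=float)
    return a / np.sqrt(a**2 + np.pi**2 / 3.0)


def mcdonald_omega(loadings) -> float:
    """omega = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2))."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("loadings must lie strictly inside (-1, 1)")
    s = lam.sum() ** 2
    return float(s / (s + (1.0 - lam**2).sum()))


def cohens_d_welch(g1: DescriptiveStats, g2: DescriptiveStats) -> GroupContrast:
    """Pooled-SD standardized mean difference with a Welch t-test.

    d uses the pooled SD; the t statistic and Satterthwaite df use the
    unpooled variances.  The d CI is the normal approximation (labelled as
    such; see package docs).
    """
    n1, n2 = g1.n, g2.n
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = g1.sd**2, g2.sd**2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero; d undefined")
    d = (g1.mean - g2.mean) / np.sqrt(sp2)
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    ci = (d - 1.959963984540054 * se_d, d + 1.959963984540054 * se_d)
    se_t = np.sqrt(v1 / n1 + v2 / n2)
    if se_t == 0:
        raise ValueError("both group variances are zero; t undefined")
    t = (g1.mean - g2.mean) / se_t
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupContrast(d=float(d), d_ci=(float(ci[0]), float(ci[1])),
                         t=float(t), df=float(df), p=float(p))


def percentile_rank(score, reference) -> float:
    """Mid-rank percentile: 100 * (#below + 0.5 * #equal) / n."""
    ref = np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("reference sample is empty")
    below = np.count_nonzero(ref < score)
    equal = np.count_nonzero(ref == score)
    return float(100.0 * (below + 0.5 * equal) / ref.size)
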