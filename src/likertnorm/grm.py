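"""Graded response model: multigroup marginal ML fitting, EAP scoring,
theta-based T-scores, and a polychoric eigenvalue screen.

The boundary curve is logistic with scale constant 1.0:
``P*(k | theta) = 1 / (1 + exp(-a * (theta - b_k)))`` and the probability of
category ``k`` (1-based) is ``P*(k-1) - P*(k)`` with ``P*(0) = 1``,
``P*(K) = 0``.

Fitting is Bock-Aitkin EM over a fixed grid of equally spaced quadrature
nodes weighted by the group's normal prior density.  Item parameters are
constrained equal across groups; the reference group's latent distribution is
fixed at N(0, 1) and the remaining groups' means/SDs are estimated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .data import ItemResponseMatrix

__all__ = [
    "GRMParameters",
    "ThetaEstimate",
    "category_probabilities",
    "boundary_probabilities",
    "fit_grm_multigroup",
    "eap_score",
    "eap_scores",
    "theta_to_t",
    "polychoric_correlation",
    "polychoric_eigen_screen",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-300


class ConvergenceError(RuntimeError):
    """Raised when an iterative routine fails irrecoverably."""


@dataclass
class GRMParameters:
    """Per-item slopes/thresholds plus per-group latent moments."""

    item_names: list[str]
    a: np.ndarray  # (I,) discriminations, > 0
    b: np.ndarray  # (I, K-1) strictly increasing thresholds
    n_categories: int
    group_means: dict[str, float]
    group_sds: dict[str, float]
    reference_group: str
    log_likelihood: float | None = None
    n_iterations: int | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.ndim != 1 or self.b.ndim != 2:
            raise ValueError("a must be 1-D and b 2-D")
        if self.b.shape != (self.a.size, self.n_categories - 1):
            raise ValueError("b must have shape (n_items, n_categories - 1)")
        if np.any(self.a <= 0):
            raise ValueError("discriminations must be positive")
        if np.any(np.diff(self.b, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        ref = self.reference_group
        if ref not in self.group_means:
            raise ValueError(f"reference group {ref!r} missing from group_means")
        if self.group_means[ref] != 0.0 or self.group_sds[ref] != 1.0:
            raise ValueError("reference group latent moments must be exactly (0, 1)")
        for g, s in self.group_sds.items():
            if s <= 0:
                raise ValueError(f"group {g!r} latent SD must be positive")

    @property
    def n_items(self) -> int:
        return self.a.size

    def to_dict(self) -> dict:
        return {
            "schema": "grm-parameters/1",
            "n_categories": self.n_categories,
            "reference_group": self.reference_group,
            "items": [
                {
                    "name": n,
                    "a": float(f"{ai:.12g}"),
                    "b": [float(f"{x:.12g}") for x in bi],
                }
                for n, ai, bi in zip(self.item_names, self.a, self.b)
            ],
            "groups": {
                g: {
                    "mean": float(f"{self.group_means[g]:.12g}"),
                    "sd": float(f"{self.group_sds[g]:.12g}"),
                }
                for g in self.group_means
            },
            "fit": {
                "log_likelihood": self.log_likelihood,
                "n_iterations": self.n_iterations,
                "converged": self.converged,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRMParameters":
        items = d["items"]
        fit = d.get("fit", {})
        return cls(
            item_names=[it["name"] for it in items],
            a=np.array([it["a"] for it in items], dtype=float),
            b=np.array([it["b"] for it in items], dtype=float),
            n_categories=int(d["n_categories"]),
            group_means={g: float(v["mean"]) for g, v in d["groups"].items()},
            group_sds={g: float(v["sd"]) for g, v in d["groups"].items()},
            reference_group=d["reference_group"],
            log_likelihood=fit.get("log_likelihood"),
            n_iterations=fit.get("n_iterations"),
            converged=fit.get("converged"),
        )


@dataclass
class ThetaEstimate:
    """EAP posterior summary for one response pattern."""

    theta: float
    se: float
    t_irt: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("posterior SD must be positive")
        self.t_irt = theta_to_t(self.theta)


def theta_to_t(theta):
    """Affine map from the latent metric to T units: ``T = 10*theta + 50``."""
    return 10.0 * np.asarray(theta, dtype=float) + 50.0


def boundary_probabilities(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Logistic boundary curves ``P*(k|theta)``; shape (len(theta), K-1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return expit(a * (theta[:, None] - np.asarray(b, dtype=float)[None, :]))


def category_probabilities(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities ``P(X=k|theta)`` for k=1..K; shape (len(theta), K)."""
    pstar = boundary_probabilities(a, b, theta)
    n, km1 = pstar.shape
    full = np.empty((n, km1 + 2))
    full[:, 0] = 1.0
    full[:, 1:-1] = pstar
    full[:, -1] = 0.0
    return full[:, :-1] - full[:, 1:]


def _prob_table(a: np.ndarray, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """log P(X=k|theta_q) for all items; shape (I, K, Q)."""
    I, km1 = b.shape
    out = np.empty((I, km1 + 1, nodes.size))
    for i in range(I):
        out[i] = category_probabilities(a[i], b[i], nodes).T
    return np.log(np.clip(out, _PROB_FLOOR, None))


# --------------------------------------------------------------------------
# EM fitting
# --------------------------------------------------------------------------


def _item_objective(z, r, nodes):
    """Negative expected complete-data log-likelihood for one item, with
    analytic gradient, in the unconstrained parameterization
    z = (log a, b_1, log(b_2-b_1), ..., log(b_{K-1}-b_{K-2}))."""
    km1 = r.shape[0] - 1
    a = np.exp(z[0])
    gaps = np.exp(z[2 : 2 + km1 - 1])
    b = np.concatenate([[z[1]], z[1] + np.cumsum(gaps)])
    pstar = expit(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
    p = np.empty((km1 + 1, nodes.size))
    p[0] = 1.0 - pstar[0]
    p[1:-1] = pstar[:-1] - pstar[1:]
    p[-1] = pstar[-1]
    p_safe = np.clip(p, 1e-12, None)
    f = float((r * np.log(p_safe)).sum())

    # dL/dP*_k = r_{k+1}/p_{k+1} - r_k/p_k   (category index shifted by 1)
    ratio = r / p_safe
    G = ratio[1:] - ratio[:-1]  # (K-1, Q)
    S = pstar * (1.0 - pstar)
    GS = G * S
    df_da = float((GS * (nodes[None, :] - b[:, None])).sum())
    df_db = -a * GS.sum(axis=1)  # (K-1,)
    grad = np.empty_like(z)
    grad[0] = a * df_da
    grad[1] = df_db.sum()
    if km1 > 1:
        tail = np.cumsum(df_db[::-1])[::-1]  # sum_{k>=j} df_db_k
        grad[2:] = gaps * tail[1:]
    return -f, -grad


def _pack_item(a_i: float, b_i: np.ndarray) -> np.ndarray:
    gaps = np.diff(b_i)
    return np.concatenate([[np.log(a_i)], [b_i[0]], np.log(gaps)])


def _unpack_item(z: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(z[0]))
    b = np.concatenate([[z[1]], z[1] + np.cumsum(np.exp(z[2:]))])
    return a, b


def _start_values(X: np.ndarray, n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Discriminations 1.0; thresholds from inverse-normal cumulative props."""
    I = X.shape[1]
    a = np.ones(I)
    b = np.empty((I, n_categories - 1))
    for i in range(I):
        x = X[:, i]
        x = x[~np.isnan(x)]
        n = x.size
        cum = np.array([(x <= k).sum() for k in range(1, n_categories)]) / n
        cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
        bi = stats.norm.ppf(cum)
        # enforce strict ordering for flat stretches
        for j in range(1, bi.size):
            if bi[j] <= bi[j - 1]:
                bi[j] = bi[j - 1] + 1e-3
        b[i] = bi
    return a, b


def fit_grm_multigroup(
    data: ItemResponseMatrix,
    n_quadrature: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
    tol: float = 1e-4,
    max_iter: int = 500,
    reference_group: str | None = None,
) -> GRMParameters:
    """Fit a multigroup GRM by Bock-Aitkin EM on a fixed quadrature grid.

    Item parameters are shared across groups; the reference group's latent
    distribution is fixed at N(0, 1) and all other groups' means and SDs are
    estimated in the M-step from posterior moments.

    Raises
    ------
    ValueError
        If any item has fewer than two observed categories.
    """
    X = data.responses - data.min_category + 1  # recode to 1..K
    K = data.n_categories
    for i, name in enumerate(data.item_names):
        obs = X[:, i][~np.isnan(X[:, i])]
        if np.unique(obs).size < 2:
            raise ValueError(
                f"item {name!r} has fewer than two observed categories; cannot fit"
            )
    groups = data.groups
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present in data")

    nodes = np.linspace(quad_range[0], quad_range[1], n_quadrature)
    glabels = np.asarray([str(g) for g in data.group])
    gmasks = {g: glabels == g for g in groups}

    # one-hot response indicators per item: list of (n, K) with NaN rows zero
    onehot = []
    for i in range(X.shape[1]):
        col = X[:, i]
        oh = np.zeros((X.shape[0], K))
        m = ~np.isnan(col)
        oh[np.nonzero(m)[0], (col[m] - 1).astype(int)] = 1.0
        onehot.append(oh)

    a, b = _start_values(X, K)
    mu = {g: 0.0 for g in groups}
    sd = {g: 1.0 for g in groups}

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logP = _prob_table(a, b, nodes)  # (I, K, Q)

        # per-respondent log-likelihood over nodes
        L = np.zeros((X.shape[0], n_quadrature))
        for i in range(X.shape[1]):
            col = X[:, i]
            m = ~np.isnan(col)
            L[m] += logP[i, (col[m] - 1).astype(int), :]

        post = np.empty_like(L)
        ll = 0.0
        for g in groups:
            mask = gmasks[g]
            logw = stats.norm.logpdf(nodes, loc=mu[g], scale=sd[g])
            logw -= logsumexp(logw)
            Lg = L[mask] + logw[None, :]
            norm = logsumexp(Lg, axis=1)
            ll += float(norm.sum())
            post[mask] = np.exp(Lg - norm[:, None])

        # expected category counts r[i, k, q]
        r = np.empty((X.shape[1], K, n_quadrature))
        for i in range(X.shape[1]):
            r[i] = onehot[i].T @ post

        # M-step: items
        a_new = np.empty_like(a)
        b_new = np.empty_like(b)
        for i in range(X.shape[1]):
            z0 = _pack_item(a[i], b[i])
            res = optimize.minimize(
                _item_objective,
                z0,
                args=(r[i], nodes),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
            )
            a_new[i], b_new[i] = _unpack_item(res.x)

        # M-step: non-reference group moments from posterior theta moments
        mu_new = dict(mu)
        sd_new = dict(sd)
        for g in groups:
            if g == reference_group:
                continue
            pg = post[gmasks[g]]
            m1 = float((pg @ nodes).mean())
            m2 = float((pg @ nodes**2).mean())
            var = max(m2 - m1 * m1, 1e-6)
            mu_new[g] = m1
            sd_new[g] = np.sqrt(var)

        delta = max(
            np.abs(a_new - a).max(),
            np.abs(b_new - b).max(),
            max(
                (abs(mu_new[g] - mu[g]) for g in groups if g != reference_group),
                default=0.0,
            ),
            max(
                (abs(sd_new[g] - sd[g]) for g in groups if g != reference_group),
                default=0.0,
            ),
        )
        if ll < prev_ll - 1e-8:
            warnings.warn(
                f"EM log-likelihood decreased at iteration {it} "
                f"({prev_ll:.6f} -> {ll:.6f})",
                RuntimeWarning,
            )
        prev_ll = ll
        a, b = a_new, b_new
        mu, sd = mu_new, sd_new
        if delta < tol:
            converged = True
            break

    if not converged:
        logger.warning("EM did not converge in %d iterations (delta tol %.2g)", max_iter, tol)

    mu[reference_group] = 0.0
    sd[reference_group] = 1.0
    return GRMParameters(
        item_names=list(data.item_names),
        a=a,
        b=b,
        n_categories=K,
        group_means=mu,
        group_sds=sd,
        reference_group=reference_group,
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
    )


# --------------------------------------------------------------------------
# EAP scoring
# --------------------------------------------------------------------------


def _posterior_grid(
    pattern: np.ndarray,
    params: GRMParameters,
    group: str,
    nodes: np.ndarray,
) -> np.ndarray:
    logw = stats.norm.logpdf(nodes, loc=params.group_means[group], scale=params.group_sds[group])
    logP = _prob_table(params.a, params.b, nodes)
    L = logw.copy()
    any_obs = False
    for i, x in enumerate(pattern):
        if np.isnan(x):
            continue
        any_obs = True
        k = int(x) - 1
        if not 0 <= k < params.n_categories:
            raise ValueError(f"response {x} invalid for item {params.item_names[i]}")
        L = L + logP[i, k, :]
    if not any_obs:
        raise ValueError("cannot score an all-missing response pattern")
    L -= logsumexp(L)
    return np.exp(L)


def eap_score(
    pattern,
    params: GRMParameters,
    group: str | None = None,
    n_quadrature: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
) -> ThetaEstimate:
    """Expected-a-posteriori latent score for one response pattern.

    The posterior is the group's normal prior times the pattern likelihood,
    evaluated on the same fixed quadrature grid used for fitting.
    """
    if group is None:
        group = params.reference_group
    pattern = np.asarray(pattern, dtype=float)
    nodes = np.linspace(quad_range[0], quad_range[1], n_quadrature)
    w = _posterior_grid(pattern, params, group, nodes)
    mean = float(w @ nodes)
    var = float(w @ (nodes - mean) ** 2)
    return ThetaEstimate(theta=mean, se=float(np.sqrt(max(var, 1e-300))))


def eap_scores(
    data: ItemResponseMatrix,
    params: GRMParameters,
    n_quadrature: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
) -> np.ndarray:
    """Vectorized EAP over a whole matrix; returns (n, 2) array of (theta, se)."""
    nodes = np.linspace(quad_range[0], quad_range[1], n_quadrature)
    logP = _prob_table(params.a, params.b, nodes)
    X = data.responses - data.min_category + 1
    L = np.zeros((X.shape[0], nodes.size))
    for i in range(X.shape[1]):
        col = X[:, i]
        m = ~np.isnan(col)
        L[m] += logP[i, (col[m] - 1).astype(int), :]
    out = np.empty((X.shape[0], 2))
    glabels = np.asarray([str(g) for g in data.group])
    for g in data.groups:
        mask = glabels == g
        logw = stats.norm.logpdf(nodes, loc=params.group_means[g], scale=params.group_sds[g])
        Lg = L[mask] + logw[None, :]
        Lg -= logsumexp(Lg, axis=1)[:, None]
        w = np.exp(Lg)
        mean = w @ nodes
        var = (w * (nodes[None, :] - mean[:, None]) ** 2).sum(axis=1)
        out[mask, 0] = mean
        out[mask, 1] = np.sqrt(np.clip(var, 1e-300, None))
    return out


# --------------------------------------------------------------------------
# Polychoric eigenvalue screen
# --------------------------------------------------------------------------


def _bvn_cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a standard bivariate normal on the grid of
    thresholds (augmented with +-inf); shape (len(tx)+1, len(ty)+1)."""
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    C = np.zeros((gx.size, gy.size))
    # boundaries: CDF collapses to marginals / constants at +-inf
    C[-1, -1] = 1.0
    C[-1, 1:-1] = stats.norm.cdf(gy[1:-1])
    C[1:-1, -1] = stats.norm.cdf(gx[1:-1])
    if gx.size > 2 and gy.size > 2:
        XX, YY = np.meshgrid(gx[1:-1], gy[1:-1], indexing="ij")
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        vals = stats.multivariate_normal.cdf(pts, mean=[0.0, 0.0], cov=cov)
        C[1:-1, 1:-1] = np.asarray(vals).reshape(XX.shape)
    return np.clip(C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1], 0.0, 1.0)


def polychoric_correlation(
    x: np.ndarray, y: np.ndarray, n_categories: int
) -> float:
    """Two-step ML polychoric correlation between two ordinal variables
    (categories coded 1..K).  Falls back to Spearman with a warning when the
    contingency table is degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[m].astype(int), y[m].astype(int)
    table = np.zeros((n_categories, n_categories))
    np.add.at(table, (x - 1, y - 1), 1.0)
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if rows.sum() < 2 or cols.sum() < 2:
        warnings.warn(
            "degenerate contingency table; falling back to Spearman correlation",
            RuntimeWarning,
        )
        return float(stats.spearmanr(x, y).statistic)
    # collapse unobserved categories, then take thresholds from the margins
    table = table[np.ix_(rows, cols)]
    px = table.sum(axis=1) / table.sum()
    py = table.sum(axis=0) / table.sum()
    tx = stats.norm.ppf(np.clip(np.cumsum(px)[:-1], 1e-10, 1 - 1e-10))
    ty = stats.norm.ppf(np.clip(np.cumsum(py)[:-1], 1e-10, 1 - 1e-10))

    def negll(rho: float) -> float:
        p = np.clip(_bvn_cell_probs(tx, ty, rho), 1e-12, None)
        return -float((table * np.log(p)).sum())

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_eigen_screen(data: ItemResponseMatrix) -> np.ndarray:
    """Descending eigenvalues of the items' polychoric correlation matrix."""
    if data.n_items < 3:
        raise ValueError("need at least three items for an eigenvalue screen")
    X = data.responses - data.min_category + 1
    I = data.n_items
    R = np.eye(I)
    for i in range(I):
        for j in range(i + 1, I):
            r = polychoric_correlation(X[:, i], X[:, j], data.n_categories)
            R[i, j] = R[j, i] = r
    return np.sort(np.linalg.eigvalsh(R))[::-1]
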