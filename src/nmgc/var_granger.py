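"""Vector-autoregressive modeling and temporal Granger causality.

Granger causality (GC) from channel j to channel i is the log-ratio of
restricted to unrestricted prediction-error variances,

    GC_{j->i} = ln( V_restricted / V_unrestricted ),

where the restricted model predicts x_i from p lags of x_i (and, in the
conditional formulation, p lags of every other channel except j), and the
unrestricted model adds the p lags of x_j.  Both models are fitted by
per-equation ordinary least squares with intercept on the identical target
window (the first p samples are dropped once), which makes the models
exactly nested and hence guarantees GC >= 0.

With exactly two channels the conditional and unconditional formulations
coincide.  With more channels the conditional form removes common-driver
and chain confounds by conditioning on the remaining channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import inference
from .preprocess import TimeSeriesSet

__all__ = [
    "VARModel",
    "GCResult",
    "GrangerCausality",
    "fit_var",
    "select_order_aic",
    "gc_unconditional",
    "gc_conditional",
    "gc_matrix",
]

MODES = ("unconditional", "conditional")


@dataclass
class VARModel:
    """A fitted vector-autoregression.

    A[l] is the (k x k) coefficient block at lag l+1; ``resid_var`` holds the
    per-equation residual variances (RSS / n_obs) entering the GC log-ratio.
    """

    order: int
    coefs: np.ndarray  # (p, k, k): coefs[l, i, j] = effect of x_j(t-l-1) on x_i(t)
    intercept: np.ndarray  # (k,)
    resid_cov: np.ndarray  # (k, k), MLE normalization
    resid_var: np.ndarray  # (k,)
    n_obs: int
    aic: float
    labels: tuple[str, ...] = ()
    residuals: np.ndarray | None = None


@dataclass
class GCResult:
    """Directed GC matrix: entry [i, j] is GC from channel j to channel i."""

    gc: np.ndarray
    mode: str
    order: int
    F: np.ndarray
    pval: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.05
    labels: tuple[str, ...] = ()
    n_obs: int = 0


def _as_matrix(ts) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(ts, TimeSeriesSet):
        return ts.data, ts.labels
    x = np.asarray(ts, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x, tuple(f"ch{i}" for i in range(x.shape[1]))


def _lagged_design(X: np.ndarray, p: int, cols) -> np.ndarray:
    """Design matrix [1, x_c(t-1) .. x_c(t-p) for c in cols], rows t = p..n-1."""
    n = X.shape[0]
    cols = list(cols)
    Z = np.empty((n - p, 1 + p * len(cols)))
    Z[:, 0] = 1.0
    k = 1
    for c in cols:
        for lag in range(1, p + 1):
            Z[:, k] = X[p - lag : n - lag, c]
            k += 1
    return Z


def _ols_rss(Z: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of y on Z; rejects rank-deficient designs."""
    beta, rss, rank, sv = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < {Z.shape[1]}, cond {cond:.3g})"
        )
    if rss.size:
        return float(rss[0])
    r = y - Z @ beta
    return float(r @ r)


def fit_var(ts, channels=None, p: int = 15) -> VARModel:
    """Fit a VAR(p) by per-equation OLS with intercept.

    Residual variances use the MLE normalization RSS / n_obs with
    n_obs = n_samples - p.
    """
    X, labels = _as_matrix(ts)
    if channels is not None:
        channels = list(channels)
        X = X[:, channels]
        labels = tuple(labels[c] for c in channels)
    n, k = X.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if n <= p * k + 10:
        raise ValueError(f"insufficient samples ({n}) for VAR({p}) on {k} channels")
    Z = _lagged_design(X, p, range(k))
    Y = X[p:]
    beta, _, rank, sv = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < {Z.shape[1]}, cond {cond:.3g})"
        )
    resid = Y - Z @ beta
    n_obs = n - p
    cov = resid.T @ resid / n_obs
    intercept = beta[0]
    coefs = np.empty((p, k, k))
    for c in range(k):
        for lag in range(p):
            coefs[lag, :, c] = beta[1 + c * p + lag]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        logdet = -np.inf
    aic = float(logdet + 2.0 * (k * k * p + k) / n_obs)
    return VARModel(
        order=p, coefs=coefs, intercept=intercept, resid_cov=cov,
        resid_var=np.diag(cov).copy(), n_obs=n_obs, aic=aic, labels=labels,
        residuals=resid,
    )


def select_order_aic(ts, p_max: int = 30, channels=None) -> int:
    """Akaike-criterion order selection for the full-system VAR.

    Every candidate order is fitted on the common sample window implied by
    ``p_max`` so the criteria are comparable; returns the argmin of
    ln det(Sigma) + 2 k^2 p / n_obs over p in 1..p_max.
    """
    X, _ = _as_matrix(ts)
    if channels is not None:
        X = X[:, list(channels)]
    n, k = X.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if n <= p_max * k + 10:
        raise ValueError(f"insufficient samples ({n}) for p_max={p_max} on {k} channels")
    best_p, best_aic = 1, np.inf
    Y = X[p_max:]
    n_obs = n - p_max
    Zfull = _lagged_design(X, p_max, range(k))
    for p in range(1, p_max + 1):
        # columns of Zfull are grouped per channel; keep the first p lags of each
        keep = [0] + [1 + c * p_max + lag for c in range(k) for lag in range(p)]
        Z = Zfull[:, keep]
        beta, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
        if rank < Z.shape[1]:
            continue
        resid = Y - Z @ beta
        cov = resid.T @ resid / n_obs
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            continue
        aic = logdet + 2.0 * (k * k * p + k) / n_obs
        if aic < best_aic:
            best_p, best_aic = p, aic
    return best_p


def _gc_pair(X: np.ndarray, j: int, i: int, p: int, mode: str) -> tuple[float, float, float]:
    """(GC, F, p-value) for the directed pair j -> i."""
    n, k = X.shape
    if i == j:
        raise ValueError("GC of a channel onto itself is undefined")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "conditional":
        cols_r = [c for c in range(k) if c != j]
    else:
        cols_r = [i]
    cols_u = cols_r + [j]
    y = X[p:, i]
    rss_r = _ols_rss(_lagged_design(X, p, cols_r), y)
    rss_u = _ols_rss(_lagged_design(X, p, cols_u), y)
    n_obs = n - p
    if rss_u <= 0 or rss_r <= 0:
        raise ValueError("degenerate (zero) residual variance")
    gc = float(np.log(rss_r / rss_u))
    dof_u = n_obs - (1 + p * len(cols_u))
    F, pv = inference.gc_f_test(max(rss_r, rss_u), rss_u, q=p, dof_u=dof_u)
    return gc, F, pv


def gc_unconditional(ts, j: int, i: int, p: int = 15) -> float:
    """Pairwise-unconditional GC from channel j to channel i."""
    X, _ = _as_matrix(ts)
    return _gc_pair(X, j, i, p, "unconditional")[0]


def gc_conditional(ts, j: int, i: int, p: int = 15) -> float:
    """Pairwise-conditional GC from j to i given all remaining channels."""
    X, _ = _as_matrix(ts)
    if X.shape[1] < 2:
        raise ValueError("conditional GC needs at least 2 channels")
    return _gc_pair(X, j, i, p, "conditional")[0]


def gc_matrix(ts, p: int = 15, mode: str = "conditional", alpha: float = 0.05,
              corrections=inference.CORRECTIONS) -> GCResult:
    """All n(n-1) directed GC values with F statistics and significance masks.

    The multiple-testing family is the set of off-diagonal pairs of this
    single trial.
    """
    X, labels = _as_matrix(ts)
    n, k = X.shape
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    gc = np.full((k, k), np.nan)
    F = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            gc[i, j], F[i, j], pv[i, j] = _gc_pair(X, j, i, p, mode)
    masks = inference.significance_masks(pv, alpha=alpha, corrections=corrections)
    return GCResult(
        gc=gc, mode=mode, order=p, F=F, pval=pv, masks=masks, alpha=alpha,
        labels=labels, n_obs=n - p,
    )


class GrangerCausality(BaseEstimator):
    """Directed Granger-causality estimation as a scikit-learn estimator.

    Parameters
    ----------
    order : AR model order (lags).  ``order='aic'`` selects it by the Akaike
        criterion up to ``max_order``.
    mode : 'conditional' or 'unconditional' formulation.
    alpha : nominal significance level of the per-pair F tests.
    corrections : multiple-testing corrections to evaluate over the family
        of all directed pairs.

    Attributes (after ``fit``)
    ----------
    gc_ : (k, k) GC matrix, entry [i, j] = GC from channel j to channel i.
    F_, pval_ : matching F statistics and p-values.
    masks_ : dict of boolean significance masks per correction.
    order_ : the order actually used.
    """

    def __init__(self, order=15, mode: str = "conditional", alpha: float = 0.05,
                 corrections=inference.CORRECTIONS, max_order: int = 30):
        self.order = order
        self.mode = mode
        self.alpha = alpha
        self.corrections = corrections
        self.max_order = max_order

    def fit(self, X, y=None):
        X_mat, labels = _as_matrix(X)
        if X_mat.shape[1] < 2:
            raise ValueError("GrangerCausality requires at least 2 channels")
        if self.order == "aic":
            p = select_order_aic(X_mat, p_max=self.max_order)
        else:
            p = int(self.order)
        res = gc_matrix(X_mat, p=p, mode=self.mode, alpha=self.alpha,
                        corrections=self.corrections)
        self.result_ = res
        self.gc_ = res.gc
        self.F_ = res.F
        self.pval_ = res.pval
        self.masks_ = res.masks
        self.order_ = p
        self.labels_ = labels
        self.n_obs_ = res.n_obs
        return self

    def transform(self, X=None):
        """Return the fitted GC matrix (analysis estimator: X is ignored)."""
        if not hasattr(self, "gc_"):
            raise AttributeError("GrangerCausality instance is not fitted yet")
        return self.gc_
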