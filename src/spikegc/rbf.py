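"""Radial-basis-function regression: k-means centers, kNN widths, MSE weights.

The nonlinear predictor used throughout the package is a linear combination of
radial basis functions,

    y = w_0 + sum_i w_i Phi(||X - c_i||),

with three kernel families:

* ``gf``   (Gaussian):             Phi(r) = exp(-r^2 / (2 sigma^2))
* ``rsf``  (reflected sigmoidal):  Phi(r) = 1 / (1 + exp(r^2 / sigma^2))
* ``imqf`` (inverse multiquadric): Phi(r) = 1 / sqrt(r^2 + sigma^2)

The three free parameter groups are learned in sequence: centers ``c_i`` by
k-means, a single shared width ``sigma`` by a k-nearest-neighbour rule over
the centers, and the output weights by (ridge-stabilised) least squares.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "KERNELS",
    "kernel_value",
    "kernel_matrix",
    "fit_centers",
    "estimate_width",
    "fit_weights",
    "auto_n_centers",
    "RBFFeatures",
    "RBFRegressor",
]

KERNELS = ("gf", "rsf", "imqf")

#: width floor used when all centers coincide
_SIGMA_FLOOR = 1e-6


def kernel_value(kind: str, r, sigma: float):
    """Evaluate one RBF kernel at distance(s) ``r`` with shared width ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if kind not in KERNELS:
        raise ValueError(f"unknown kernel {kind!r}; choose from {KERNELS}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    r2 = r * r
    if kind == "gf":
        return np.exp(-r2 / (2.0 * sigma**2))
    if kind == "rsf":
        # 1/(1+exp(u)) == expit(-u), overflow-safe
        return expit(-r2 / sigma**2)
    return 1.0 / np.sqrt(r2 + sigma**2)


def kernel_matrix(kind: str, x: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Basis-evaluation matrix Phi with Phi[k, i] = kernel(||x_k - c_i||)."""
    d = cdist(np.atleast_2d(x), np.atleast_2d(centers))
    return kernel_value(kind, d, sigma)


def auto_n_centers(n_samples: int, p_max: int = 20) -> int:
    """Default center count: min(p_max, max(4, round(sqrt(N)/2)))."""
    return int(min(p_max, max(4, round(np.sqrt(n_samples) / 2.0))))


def fit_centers(data: np.ndarray, p: int, seed: int | None = None) -> np.ndarray:
    """k-means centers of the lag-vector cloud (k-means++ init, 5 restarts)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_distinct = np.unique(data, axis=0).shape[0]
    if p > n_distinct:
        raise ValueError(
            f"requested p={p} centers but data has only {n_distinct} distinct "
            f"vectors; lower p"
        )
    if p < 1:
        raise ValueError("p must be >= 1")
    km = KMeans(
        n_clusters=p,
        init="k-means++",
        n_init=5,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        km.fit(data)
    return km.cluster_centers_


def estimate_width(centers: np.ndarray, k_nn: int = 2) -> float:
    """Shared RBF width from the centers: mean distance to k nearest centers.

    For each center, take the mean distance to its ``k_nn`` nearest *other*
    centers (``k_nn`` clipped to p-1), then average over centers.  Falls back
    to a small positive floor when all centers coincide.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    p = centers.shape[0]
    if p < 2:
        raise ValueError("need at least 2 centers to estimate a width")
    k = int(min(max(k_nn, 1), p - 1))
    d = cdist(centers, centers)
    d.sort(axis=1)
    sigma = float(d[:, 1 : k + 1].mean())
    if sigma <= 0:
        warnings.warn(
            "all RBF centers coincide; using floor width", RuntimeWarning
        )
        sigma = _SIGMA_FLOOR
    return sigma


def fit_weights(design: np.ndarray, targets: np.ndarray, ridge: float = 1e-8):
    """Minimum-square-error output weights, ridge-stabilised.

    ``design`` must already contain the intercept column (first column).  The
    ridge penalty is applied to the non-intercept weights only, scaled by the
    mean diagonal of the corresponding Gram block so it acts relatively.

    Returns ``(weights, residual_variance)`` with residual_variance the mean
    squared residual.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    n, c = design.shape
    if n < c:
        raise ValueError(f"need at least as many rows ({n}) as columns ({c})")
    g = design.T @ design
    rhs = design.T @ targets
    beta = _ridge_solve(g, rhs, ridge, intercept_cols=1)
    resid = targets - design @ beta
    return beta, float(np.mean(resid**2))


def _ridge_solve(g, rhs, ridge, intercept_cols=1):
    """Solve (G + lam*J) beta = rhs, ridge on the non-intercept diagonal.

    The base penalty is the plain ``ridge`` (default 1e-8); if the Gram
    matrix is numerically singular the penalty is escalated relative to the
    Gram diagonal before giving up.
    """
    c = g.shape[0]
    diag_idx = np.arange(intercept_cols, c)
    scale = float(np.mean(np.diag(g)[diag_idx])) if diag_idx.size else 1.0
    scale = max(scale, 1e-300)
    for lam in (ridge, ridge * scale * 1e4, ridge * scale * 1e8):
        a = g.copy()
        a[diag_idx, diag_idx] += lam
        try:
            cho = linalg.cho_factor(a, lower=True, check_finite=False)
            return linalg.cho_solve(cho, rhs, check_finite=False)
        except linalg.LinAlgError:
            continue
    cond = np.linalg.cond(g)
    raise np.linalg.LinAlgError(
        f"design Gram matrix numerically singular beyond ridge rescue "
        f"(condition number {cond:.3e})"
    )


class RBFFeatures(TransformerMixin, BaseEstimator):
    """Transformer mapping vectors to their RBF basis evaluations.

    Fits k-means centers (on a seeded subsample of at most
    ``max_cluster_samples`` rows) and a shared kNN-derived width; ``transform``
    returns the (n_samples, n_centers) kernel matrix.

    Parameters
    ----------
    kernel : {"gf", "rsf", "imqf"}
    n_centers : int or "auto"
        "auto" uses ``auto_n_centers`` of the fitting-sample count, capped by
        the number of distinct vectors available.
    knn_k : int
        Neighbour count in the width rule.
    random_state : int or None
    """

    def __init__(self, kernel="gf", n_centers="auto", knn_k=2,
                 max_cluster_samples=4096, random_state=None):
        self.kernel = kernel
        self.n_centers = n_centers
        self.knn_k = knn_k
        self.max_cluster_samples = max_cluster_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        rng = np.random.default_rng(self.random_state)
        sample = X
        if X.shape[0] > self.max_cluster_samples:
            idx = rng.choice(X.shape[0], size=self.max_cluster_samples, replace=False)
            sample = X[idx]
        n_distinct = np.unique(sample, axis=0).shape[0]
        if self.n_centers == "auto":
            p = auto_n_centers(X.shape[0])
        else:
            p = int(self.n_centers)
        p = min(p, n_distinct)
        if p < 1:
            raise ValueError("no usable data to place centers on")
        seed = int(np.random.SeedSequence(self.random_state).generate_state(1)[0] & 0x7FFFFFFF)
        self.centers_ = fit_centers(sample, p, seed=seed)
        if p >= 2:
            self.sigma_ = estimate_width(self.centers_, k_nn=self.knn_k)
        else:
            # single center: width from the data spread around it
            d = cdist(sample, self.centers_).ravel()
            self.sigma_ = float(max(d.mean(), _SIGMA_FLOOR))
        self.n_centers_ = p
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "centers_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return kernel_matrix(self.kernel, X, self.centers_, self.sigma_)


class RBFRegressor(RegressorMixin, BaseEstimator):
    """RBF regression: k-means centers -> kNN width -> MSE output weights.

    Attributes (after fit): ``basis_`` (fitted :class:`RBFFeatures`),
    ``coef_``, ``intercept_``, ``residual_variance_``.
    """

    def __init__(self, kernel="gf", n_centers="auto", knn_k=2,
                 max_cluster_samples=4096, ridge=1e-8, random_state=None):
        self.kernel = kernel
        self.n_centers = n_centers
        self.knn_k = knn_k
        self.max_cluster_samples = max_cluster_samples
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.basis_ = RBFFeatures(
            kernel=self.kernel, n_centers=self.n_centers, knn_k=self.knn_k,
            max_cluster_samples=self.max_cluster_samples,
            random_state=self.random_state,
        ).fit(X)
        phi = self.basis_.transform(X)
        design = np.column_stack([np.ones(len(phi)), phi])
        w, rv = fit_weights(design, y, ridge=self.ridge)
        self.intercept_ = float(w[0])
        self.coef_ = w[1:]
        self.residual_variance_ = rv
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        phi = self.basis_.transform(X)
        return self.intercept_ + phi @ self.coef_
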