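"""Linear and nonlinear (RBF-based) conditional Granger causality.

A channel ``y`` Granger-causes a channel ``x`` when including y's past in a
regression of x's future reduces the residual variance beyond what x's own
past (and, in the conditional variant, all remaining channels' pasts)
achieves.  The causality index is

    F_{y->x} = ln(Sigma_reduced / Sigma_full)

where Sigma_full is the residual variance of the model containing y's lag
block and Sigma_reduced the variance after removing it.  The linear variant
regresses on raw lag vectors (a VAR model); the nonlinear variant replaces
each channel's lag block with its RBF basis evaluations (Gaussian, reflected
sigmoidal or inverse-multiquadric kernels, centers by k-means, shared width
by a kNN rule; see :mod:`spikegc.rbf`).

Nesting contract: the reduced model reuses the *identical* bases of the
retained blocks (same centers and width), so the models are exactly nested,
Sigma_reduced >= Sigma_full holds structurally (up to the tiny ridge), and
F >= 0.

Presence/absence of each directed influence is decided by a one-sided F-test
on the variance reduction, the standard decision rule in Granger analysis; a
circular-shift permutation test is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .rbf import (
    KERNELS,
    _SIGMA_FLOOR,
    _ridge_solve,
    auto_n_centers,
    estimate_width,
    fit_centers,
    kernel_matrix,
)

__all__ = [
    "LagEmbedding",
    "GCResult",
    "DegenerateChannelError",
    "embed",
    "significance_test",
    "linear_gc_pair",
    "nonlinear_gc_pair",
    "conditional_gc",
    "GrangerNetworkIdentifier",
]


class DegenerateChannelError(ValueError):
    """Raised when a channel has zero variance (e.g. a silent neuron)."""


@dataclass(frozen=True)
class LagEmbedding:
    """Aligned targets x^k = x_{k+m+tau} and lag rows X^k = (x_{k+m-1},...,x_k)."""

    targets: np.ndarray
    lags: np.ndarray
    m: int
    tau: int

    @property
    def n_eff(self) -> int:
        return self.targets.shape[0]


def embed(series, m: int, tau: int = 0) -> LagEmbedding:
    """Build the lag embedding of one channel.

    Row ``k`` of ``lags`` is ``(x_{k+m-1}, ..., x_k)`` (most recent first) and
    predicts ``targets[k] = x_{k+m+tau}``; ``n_eff = N - m - tau``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if m < 1:
        raise ValueError("model order m must be >= 1")
    if tau < 0:
        raise ValueError("pure delay tau must be >= 0")
    n = x.size
    n_eff = n - m - tau
    if n_eff < 1:
        raise ValueError(f"series of length {n} too short for m={m}, tau={tau}")
    lags = np.lib.stride_tricks.sliding_window_view(x, m)[:n_eff, ::-1]
    return LagEmbedding(targets=x[m + tau :].copy(), lags=np.ascontiguousarray(lags), m=m, tau=tau)


@dataclass(frozen=True)
class GCResult:
    """Outcome of one directed Granger causality test."""

    f: float
    sigma_full: float
    sigma_reduced: float
    p_value: float
    decision: bool
    df_added: int
    n_samples: int
    cross_cov: float | None = None

    @property
    def variance_ratio(self) -> float:
        """Sigma_reduced / Sigma_full (the index before the log)."""
        return float(np.exp(self.f))


def significance_test(rss_full, rss_reduced, n_samples, df_added, df_full):
    """One-sided F-test p-value for the variance reduction of a nested model.

    statistic = ((rss_reduced - rss_full)/df_added) / (rss_full/(n - df_full)).
    """
    if rss_full < 0 or rss_reduced < 0:
        raise ValueError("residual sums of squares must be nonnegative")
    if df_added <= 0 or df_full <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n_samples <= df_full:
        raise ValueError("need n_samples > df_full")
    if rss_full == 0.0:
        warnings.warn("perfect fit in full model; p-value set to 0", RuntimeWarning)
        return 0.0
    stat = max(rss_reduced - rss_full, 0.0) / df_added / (rss_full / (n_samples - df_full))
    return float(stats.f.sf(stat, df_added, n_samples - df_full))


# ---------------------------------------------------------------------------
# internal machinery: per-channel basis blocks and nested least squares
# ---------------------------------------------------------------------------


def _standardize(X):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    silent = sd == 0
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} channel(s) have zero variance (silent); "
            "their influences will be reported absent",
            RuntimeWarning,
        )
    sd = np.where(silent, 1.0, sd)
    return (X - mu) / sd, silent


def _channel_basis(lags, method, kernel, n_centers, knn_k, max_samples, seed):
    """Basis block for one channel: raw lags (linear) or RBF evaluations."""
    if method == "linear":
        return lags
    rng = np.random.default_rng(seed)
    sample = lags
    if lags.shape[0] > max_samples:
        idx = rng.choice(lags.shape[0], size=max_samples, replace=False)
        sample = lags[idx]
    distinct = np.unique(sample, axis=0)
    p = auto_n_centers(lags.shape[0]) if n_centers == "auto" else int(n_centers)
    p = min(p, distinct.shape[0])
    if p < 1:
        raise ValueError("no data to cluster")
    # when few distinct patterns exist (binary spike lags), cluster them
    # directly with multiplicity weights folded in by using the sample itself
    centers = fit_centers(sample, p, seed=seed)
    if p >= 2:
        sigma = estimate_width(centers, k_nn=knn_k)
    else:
        d = np.linalg.norm(sample - centers[0], axis=1)
        sigma = float(max(d.mean(), _SIGMA_FLOOR))
    return kernel_matrix(kernel, lags, centers, sigma)


class _NetworkDesign:
    """Shared design matrix over all channels' basis blocks.

    Column 0 is the intercept; block ``c`` occupies ``slices[c]``.  Residual
    sums of squares of any sub-model (subset of blocks) are obtained from the
    cached Gram matrix, so the full and all reduced models per target reuse
    identical bases (exact nesting).
    """

    def __init__(self, bases, targets, ridge):
        n_eff = targets.shape[0]
        cols = [np.ones((n_eff, 1))]
        self.slices = []
        start = 1
        for b in bases:
            cols.append(b)
            self.slices.append(slice(start, start + b.shape[1]))
            start += b.shape[1]
        self.design = np.hstack(cols)
        self.n_cols = start
        self.gram = self.design.T @ self.design
        self.targets = targets  # n_eff x n_channels
        self.cross = self.design.T @ targets
        self.yty = np.einsum("ij,ij->j", targets, targets)
        self.n_eff = n_eff
        self.ridge = ridge

    def block_width(self, c):
        s = self.slices[c]
        return s.stop - s.start

    def columns(self, blocks):
        idx = [0]
        for c in blocks:
            s = self.slices[c]
            idx.extend(range(s.start, s.stop))
        return np.asarray(idx)

    def rss(self, target_idx, blocks):
        """Residual sum of squares regressing target on intercept + blocks."""
        idx = self.columns(blocks)
        g = self.gram[np.ix_(idx, idx)]
        c = self.cross[idx, target_idx]
        beta = _ridge_solve(g, c, self.ridge, intercept_cols=1)
        rss = self.yty[target_idx] - 2.0 * beta @ c + beta @ g @ beta
        return max(float(rss), 0.0), idx.size

    def residuals(self, target_idx, blocks):
        idx = self.columns(blocks)
        g = self.gram[np.ix_(idx, idx)]
        c = self.cross[idx, target_idx]
        beta = _ridge_solve(g, c, self.ridge, intercept_cols=1)
        return self.targets[:, target_idx] - self.design[:, idx] @ beta


def _build_design(X, method, kernel, m, tau, n_centers, knn_k, max_samples,
                  ridge, random_state, standardize=True):
    """Standardize, embed and basis-expand every channel of a T x n series."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be 2-D (time bins x channels)")
    n_ch = X.shape[1]
    if standardize:
        Xs, silent = _standardize(X)
    else:
        Xs, silent = X, np.zeros(n_ch, dtype=bool)
    embs = [embed(Xs[:, c], m, tau) for c in range(n_ch)]
    targets = np.column_stack([e.targets for e in embs])
    seeds = np.random.SeedSequence(random_state).generate_state(n_ch) & 0x7FFFFFFF
    bases = [
        _channel_basis(embs[c].lags, method, kernel, n_centers, knn_k,
                       max_samples, int(seeds[c]))
        for c in range(n_ch)
    ]
    return _NetworkDesign(bases, targets, ridge), silent


def _gc_from_rss(rss_full, rss_reduced, n_eff, df_added, df_full, alpha,
                 cross_cov=None):
    sigma_full = rss_full / n_eff
    sigma_reduced = rss_reduced / n_eff
    f = float(np.log(rss_reduced / rss_full)) if rss_full > 0 else np.inf
    f = max(f, 0.0)
    p = significance_test(rss_full, rss_reduced, n_eff, df_added, df_full)
    return GCResult(
        f=f, sigma_full=sigma_full, sigma_reduced=sigma_reduced,
        p_value=p, decision=bool(p < alpha), df_added=df_added,
        n_samples=n_eff, cross_cov=cross_cov,
    )


def _permutation_pvalue(nd, target_idx, blocks_full, source, n_shifts, rng):
    """Circular-shift surrogate p-value for dropping `source` from the model."""
    rss_full, _ = nd.rss(target_idx, blocks_full)
    reduced_blocks = [b for b in blocks_full if b != source]
    rss_red, _ = nd.rss(target_idx, reduced_blocks)
    f_obs = np.log(max(rss_red, 1e-300) / max(rss_full, 1e-300))
    s = nd.slices[source]
    src_cols = nd.design[:, s]
    other_idx = nd.columns(reduced_blocks)
    d_other = nd.design[:, other_idx]
    g_oo = nd.gram[np.ix_(other_idx, other_idx)]
    c_o = nd.cross[other_idx, target_idx]
    y = nd.targets[:, target_idx]
    count = 0
    for _ in range(n_shifts):
        shift = int(rng.integers(1, nd.n_eff))
        sc = np.roll(src_cols, shift, axis=0)
        g_ss = sc.T @ sc
        g_so = sc.T @ d_other
        c_s = sc.T @ y
        g = np.block([[g_oo, g_so.T], [g_so, g_ss]])
        c = np.concatenate([c_o, c_s])
        beta = _ridge_solve(g, c, nd.ridge, intercept_cols=1)
        rss_s = max(float(nd.yty[target_idx] - 2.0 * beta @ c + beta @ g @ beta), 0.0)
        f_s = np.log(max(rss_red, 1e-300) / max(rss_s, 1e-300))
        if f_s >= f_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_shifts)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class GrangerNetworkIdentifier(BaseEstimator):
    """Identify the directed structure of a multichannel series.

    Runs a conditional Granger causality test for every ordered pair of
    channels and assembles the decisions into a binary adjacency matrix in
    the column-acts-row convention (``decisions_[i, j] = 1`` means channel j
    drives channel i), mirroring the ground-truth matrices of
    :mod:`spikegc.simulate`.

    Parameters
    ----------
    method : {"rbf", "linear"}
        Nonlinear (RBF basis) or linear (raw lag block / VAR) modelling.
    kernel : {"gf", "rsf", "imqf"}
        RBF kernel family (ignored for the linear method).
    order : int
        Lag-embedding model order m (default 5: 50 ms of history at 10-ms
        bins, spanning synaptic and membrane timescales).
    delay : int
        Pure delay tau between the lag block and the predicted sample.
    n_centers : int or "auto"
        RBF centers per channel block; "auto" scales with sample count and is
        capped by the number of distinct lag patterns.
    alpha : float
        Significance level of the per-pair test (no multiplicity correction).
    conditioning : {"all", "pairwise"}
        "all" conditions every test on all remaining channels (distinguishes
        direct from mediated influence); "pairwise" tests each pair in
        isolation.  With 2 channels the two coincide.
    significance : {"f", "permutation"}
        Parametric one-sided F-test, or circular-shift surrogates of the
        source block (``n_permutations`` shifts; much slower).
    ridge : float
        Relative ridge stabiliser of the least-squares fits.
    standardize : bool
        z-score each channel before embedding (recommended; makes decisions
        invariant to channel offset and scale).
    random_state : int or None
        Seeds k-means and the surrogate generator; fit is deterministic for a
        fixed integer.

    Attributes
    ----------
    decisions_ : (n, n) int array, diagonal fixed to 0
    f_matrix_, p_values_, sigma_full_, sigma_reduced_ : (n, n) float arrays
        Entry [i, j] refers to the test of channel j driving channel i;
        diagonals are NaN (F and sigmas) or 1 (p-values).
    n_eff_ : usable sample count after embedding
    """

    def __init__(self, method="rbf", kernel="gf", order=5, delay=0,
                 n_centers="auto", alpha=0.01, conditioning="all",
                 significance="f", n_permutations=200, ridge=1e-8,
                 standardize=True, knn_k=2, max_cluster_samples=4096,
                 random_state=None):
        self.method = method
        self.kernel = kernel
        self.order = order
        self.delay = delay
        self.n_centers = n_centers
        self.alpha = alpha
        self.conditioning = conditioning
        self.significance = significance
        self.n_permutations = n_permutations
        self.ridge = ridge
        self.standardize = standardize
        self.knn_k = knn_k
        self.max_cluster_samples = max_cluster_samples
        self.random_state = random_state

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (time bins x channels)")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 channels")
        if self.method not in ("rbf", "linear"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "rbf" and self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.conditioning not in ("all", "pairwise"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        n_ch = X.shape[1]
        nd, silent = _build_design(
            X, self.method, self.kernel, self.order, self.delay,
            self.n_centers, self.knn_k, self.max_cluster_samples,
            self.ridge, self.random_state, self.standardize,
        )
        self.n_eff_ = nd.n_eff
        self.block_widths_ = np.array([nd.block_width(c) for c in range(n_ch)])
        f_m = np.full((n_ch, n_ch), np.nan)
        p_m = np.ones((n_ch, n_ch))
        s_full = np.full((n_ch, n_ch), np.nan)
        s_red = np.full((n_ch, n_ch), np.nan)
        dec = np.zeros((n_ch, n_ch), dtype=np.int8)
        rng = np.random.default_rng(self.random_state)
        all_blocks = list(range(n_ch))
        for i in range(n_ch):  # target channel
            try:
                if self.conditioning == "all":
                    full_blocks = all_blocks
                    rss_full, df_full = nd.rss(i, full_blocks)
                for j in range(n_ch):  # source channel
                    if j == i:
                        continue
                    if self.conditioning == "pairwise":
                        full_blocks = [i, j]
                        rss_full, df_full = nd.rss(i, full_blocks)
                    reduced = [b for b in full_blocks if b != j]
                    rss_red, _ = nd.rss(i, reduced)
                    res = _gc_from_rss(
                        rss_full, rss_red, nd.n_eff, nd.block_width(j),
                        df_full, self.alpha,
                    )
                    if self.significance == "permutation":
                        p = _permutation_pvalue(
                            nd, i, list(full_blocks), j, self.n_permutations, rng
                        )
                        res = GCResult(
                            f=res.f, sigma_full=res.sigma_full,
                            sigma_reduced=res.sigma_reduced, p_value=p,
                            decision=bool(p < self.alpha),
                            df_added=res.df_added, n_samples=res.n_samples,
                        )
                    f_m[i, j] = res.f
                    p_m[i, j] = res.p_value
                    s_full[i, j] = res.sigma_full
                    s_red[i, j] = res.sigma_reduced
                    dec[i, j] = int(res.decision and not silent[j] and not silent[i])
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(
                    f"tests with target channel {i} failed ({exc}); "
                    "recording those influences as absent",
                    RuntimeWarning,
                )
        self.f_matrix_ = f_m
        self.p_values_ = p_m
        self.sigma_full_ = s_full
        self.sigma_reduced_ = s_red
        self.decisions_ = dec
        self.n_features_in_ = n_ch
        return self

    def predict(self, X=None):
        """Return the fitted decision matrix (column-acts-row)."""
        if not hasattr(self, "decisions_"):
            raise AttributeError("call fit first")
        return self.decisions_


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def _pair_design(x, y, method, kernel, m, tau, n_centers, knn_k, max_samples,
                 ridge, seed, standardize):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    for name, s in (("x", x), ("y", y)):
        if np.std(s) == 0:
            raise DegenerateChannelError(f"channel {name} has zero variance")
    X = np.column_stack([x, y])
    return _build_design(X, method, kernel, m, tau, n_centers, knn_k,
                         max_samples, ridge, seed, standardize)[0]


def _pair_results(nd, alpha):
    """Both directed results of a 2-channel design, with cross-covariance."""
    out = []
    e_full = [nd.residuals(0, [0, 1]), nd.residuals(1, [0, 1])]
    lam = float(np.cov(e_full[0], e_full[1])[0, 1])
    for tgt, src in ((0, 1), (1, 0)):
        rss_full, df_full = nd.rss(tgt, [0, 1])
        rss_red, _ = nd.rss(tgt, [tgt])
        res = _gc_from_rss(rss_full, rss_red, nd.n_eff, nd.block_width(src),
                           df_full, alpha, cross_cov=lam)
        out.append(res)
    return tuple(out)  # (src 1 -> tgt 0, i.e. y->x), (x->y)


def linear_gc_pair(x, y, m=5, tau=0, alpha=0.01, ridge=1e-8, standardize=True):
    """Two-variate linear Granger causality.

    Returns ``(result_y_to_x, result_x_to_y)``; each includes the full/reduced
    residual variances, F = ln(Sigma_reduced/Sigma_full), the F-test p-value
    and the residual cross-covariance Lambda_1 of the full bivariate model.
    """
    nd = _pair_design(x, y, "linear", None, m, tau, None, 2, 4096, ridge,
                      None, standardize)
    return _pair_results(nd, alpha)


def nonlinear_gc_pair(x, y, m=5, tau=0, kernel="gf", n_centers="auto",
                      seed=None, alpha=0.01, ridge=1e-8, standardize=True,
                      knn_k=2, max_cluster_samples=4096):
    """Two-variate nonlinear (RBF) Granger causality; see linear_gc_pair."""
    nd = _pair_design(x, y, "rbf", kernel, m, tau, n_centers, knn_k,
                      max_cluster_samples, ridge, seed, standardize)
    return _pair_results(nd, alpha)


def conditional_gc(series, source, target, method="rbf", kernel="gf", m=5,
                   tau=0, n_centers="auto", seed=None, alpha=0.01,
                   ridge=1e-8, standardize=True, condition="all",
                   knn_k=2, max_cluster_samples=4096):
    """Conditional Granger causality of ``source`` on ``target``.

    ``series`` is a T x n matrix (or :class:`~spikegc.simulate.BinnedSeries`);
    all channels other than source and target form the conditioning set.
    With 2 channels this degrades to the pairwise test.
    """
    data = getattr(series, "data", series)
    data = np.asarray(data, dtype=float)
    if source == target:
        raise ValueError("source and target must differ")
    est = GrangerNetworkIdentifier(
        method=method, kernel=kernel, order=m, delay=tau, n_centers=n_centers,
        alpha=alpha, conditioning=condition, ridge=ridge,
        standardize=standardize, knn_k=knn_k,
        max_cluster_samples=max_cluster_samples, random_state=seed,
    ).fit(data)
    i, j = target, source
    return GCResult(
        f=float(est.f_matrix_[i, j]),
        sigma_full=float(est.sigma_full_[i, j]),
        sigma_reduced=float(est.sigma_reduced_[i, j]),
        p_value=float(est.p_values_[i, j]),
        decision=bool(est.decisions_[i, j]),
        df_added=int(est.block_widths_[j]),
        n_samples=est.n_eff_,
    )
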