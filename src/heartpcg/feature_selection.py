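"""Feature weighting and matched-index selection.

Two complementary per-feature importance scores are computed on the deep
feature matrix:

* **NCA** (neighborhood components analysis), in its diagonal
  feature-weighting form: weights ``w`` define the metric
  ``d_w(x_i, x_j) = sum_r w_r^2 (x_ir - x_jr)^2`` and are fit by maximizing
  the expected leave-one-out soft-nearest-neighbor objective
  ``f(w) = sum_i sum_{j in class(i)} p_ij`` with
  ``p_ij = exp(-d_w(x_i, x_j)) / sum_{k != i} exp(-d_w(x_i, x_k))``,
  optionally minus an L2 penalty.  Gradient ascent with a backtracking line
  search guarantees the objective never decreases across iterations.

* **ReliefF**: starting from all-zero weights, each sampled instance R_i
  pulls its weight vector down by the range-scaled difference to its k
  nearest same-class hits and up by the prior-weighted difference to its k
  nearest misses in each other class (factor P(C)/(1 - P(class(R_i)))),
  each divided by m*k.

The matched-index selector intersects the two top-x index sets: a feature
survives only if both rankings deem it important.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)


@dataclass
class NCAParams:
    learning_rate: float = 0.1  # initial step for the line search
    max_iters: int = 100
    regularization: float | None = None  # None -> 1/N
    tol: float = 1e-6
    seed: int = 0


@dataclass
class ReliefFParams:
    k: int = 10
    m: int | None = None  # None -> all instances, sequential (deterministic)
    seed: int = 0


@dataclass
class SelectionResult:
    w_nca: np.ndarray
    w_relief: np.ndarray
    top_x: int
    matched_indices: np.ndarray  # ordered by descending NCA weight


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero_var = sd < 1e-12
    if zero_var.any():
        logger.warning("%d zero-variance features standardized with eps guard", zero_var.sum())
    return (X - mu) / np.where(zero_var, 1.0, sd)


def _encode(y) -> np.ndarray:
    _, enc = np.unique(np.asarray(y), return_inverse=True)
    return enc


def nca_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Leave-one-out soft-NN objective for diagonal weights (direct form)."""
    f, _ = _nca_objective_grad(w, X, y, lam, want_grad=False)
    return f


def _nca_objective_grad(w, X, y, lam, want_grad=True):
    # scale columns by w once: squared euclidean on (X * w) gives
    # sum_r w_r^2 (x_ir - x_jr)^2, the diagonal-metric distance
    U = X * w
    d = squareform(pdist(U, metric="sqeuclidean"))
    np.fill_diagonal(d, np.inf)  # exclude self from the softmax
    e = np.exp(-(d - d.min(axis=1, keepdims=True)))
    np.fill_diagonal(e, 0.0)
    P = e / e.sum(axis=1, keepdims=True)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    p_i = (P * same).sum(axis=1)
    f = float(p_i.sum()) - lam * float(w @ w)
    if not want_grad:
        return f, None
    # df/dw_r = 2 w_r * sum_i [ p_i * sum_k P_ik z_ikr - sum_{j same} P_ij z_ijr ]
    # with z_ijr = (x_ir - x_jr)^2, expanded via matrix products.
    A = P * p_i[:, None] - P * same
    X2 = X ** 2
    s = (
        A.sum(axis=1) @ X2
        + A.sum(axis=0) @ X2
        - 2.0 * np.einsum("nd,nd->d", X, A @ X)
    )
    grad = 2.0 * w * s - 2.0 * lam * w
    return f, grad


def nca_weights(
    X: np.ndarray, y, params: NCAParams | None = None
) -> np.ndarray:
    """Per-feature NCA importance weights (``w_r^2``, all >= 0).

    Features are standardized internally; weights start at 1 (symmetric, so
    duplicated features stay exactly tied) and are updated by gradient
    ascent with backtracking so the objective is non-decreasing.
    """
    params = params or NCAParams()
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains NaN/Inf")
    y = _encode(y)
    if np.unique(y).size < 2:
        raise ValueError("NCA requires at least two classes")
    Xs = _standardize(X)
    n, d = Xs.shape
    lam = (1.0 / n) if params.regularization is None else params.regularization

    w = np.ones(d)
    step = params.learning_rate
    f, g = _nca_objective_grad(w, Xs, y, lam)
    for _ in range(params.max_iters):
        gnorm = np.linalg.norm(g)
        if gnorm < params.tol:
            break
        direction = g / gnorm
        # backtracking line search on the ascent direction
        improved = False
        for _ in range(30):
            w_new = w + step * direction
            f_new, g_new = _nca_objective_grad(w_new, Xs, y, lam)
            if f_new >= f:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if f_new - f < params.tol * max(abs(f), 1.0):
            w, f, g = w_new, f_new, g_new
            break
        w, f, g = w_new, f_new, g_new
        step *= 1.2
    return w ** 2


def relieff_weights(
    X: np.ndarray, y, params: ReliefFParams | None = None
) -> np.ndarray:
    """ReliefF per-feature weights in [-1, 1].

    ``diff`` is the absolute difference scaled by the feature's range over
    the data (constant features therefore score exactly 0).  Neighbors are
    found by Manhattan distance on the scaled features, ties broken toward
    the lowest index, self excluded from hits.  With ``m = None`` every
    instance is used once in order, making the result deterministic.
    """
    params = params or ReliefFParams()
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains NaN/Inf")
    y = _encode(y)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    for c, cnt in zip(classes, counts):
        if params.k >= cnt:
            raise ValueError(
                f"k={params.k} must be smaller than class {c} size ({cnt})"
            )
    priors = counts / n

    rng_range = X.max(axis=0) - X.min(axis=0)
    safe_range = np.where(rng_range < 1e-12, 1.0, rng_range)
    Xs = X / safe_range  # diff(a, i, j) = |Xs[i,a] - Xs[j,a]|, in [0, 1]
    Xs = Xs * (rng_range >= 1e-12)  # constant features contribute nothing

    if params.m is None:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(params.seed)
        sample_idx = rng.choice(n, size=params.m, replace=False)
    m, k = len(sample_idx), params.k

    # pairwise Manhattan distances on the scaled features
    dist = np.zeros((n, n))
    for start in range(0, n, 64):  # chunked to bound memory at large n
        sl = slice(start, min(start + 64, n))
        dist[sl] = np.abs(Xs[sl, None, :] - Xs[None, :, :]).sum(axis=2)

    W = np.zeros(d)
    for i in sample_idx:
        order = np.argsort(dist[i], kind="stable")  # stable -> lowest index ties
        ci = y[i]
        hits = [j for j in order if j != i and y[j] == ci][:k]
        W -= np.abs(Xs[hits] - Xs[i]).sum(axis=0) / (m * k)
        for c in classes:
            if c == ci:
                continue
            misses = [j for j in order if y[j] == c][:k]
            factor = priors[c] / (1.0 - priors[ci])
            W += factor * np.abs(Xs[misses] - Xs[i]).sum(axis=0) / (m * k)
    return W


def top_indices(weights: np.ndarray, top_x: int) -> np.ndarray:
    """Indices of the ``top_x`` largest weights, descending; boundary ties
    resolved toward the lowest feature index."""
    order = np.lexsort((np.arange(len(weights)), -weights))
    return order[:top_x]


def nrbmi_select(
    w_nca: np.ndarray, w_relief: np.ndarray, top_x: int = 300
) -> SelectionResult:
    """Intersect the top-x index sets of the two rankings.

    The matched set is ordered by descending NCA weight.  An empty
    intersection is permitted (warned, not fatal).
    """
    w_nca = np.asarray(w_nca, dtype=np.float64)
    w_relief = np.asarray(w_relief, dtype=np.float64)
    if w_nca.shape != w_relief.shape:
        raise ValueError(
            f"weight vectors differ in length: {w_nca.shape} vs {w_relief.shape}"
        )
    if not 1 <= top_x <= len(w_nca):
        raise ValueError(f"top_x must be in [1, {len(w_nca)}]")
    top_nca = top_indices(w_nca, top_x)
    top_rel = set(top_indices(w_relief, top_x).tolist())
    matched = np.array([i for i in top_nca if i in top_rel], dtype=int)
    if matched.size == 0:
        logger.warning("NRBMI: top-%d sets are disjoint; empty selection", top_x)
    return SelectionResult(
        w_nca=w_nca, w_relief=w_relief, top_x=top_x, matched_indices=matched
    )
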