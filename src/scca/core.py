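"""Rank-one sparse CCA solver via penalized matrix decomposition.

Diagonal-penalized sparse canonical correlation analysis: given two
column-standardized views ``X1`` (n x p1) and ``X2`` (n x p2) measured on the
same n samples, find weight vectors u, v maximizing the bilinear form
``u' X1' X2 v`` subject to ``||u||_2 <= 1``, ``||v||_2 <= 1``, per-view L1
budgets ``||u||_1 <= c1*sqrt(p1)``, ``||v||_1 <= c2*sqrt(p2)`` and, by
default, nonnegative weights.  Replacing each view's covariance matrix by its
diagonal (the identity, after standardization) makes the problem well posed
when the number of features far exceeds the number of samples, as is typical
for voxel-wise neuroimaging matrices.

The solver alternates closed-form updates of u and v, each an L1-constrained
projection of a matrix-vector product with the (deflated) cross-product
matrix ``Z = X1' X2``.  ``Z`` is materialized only when small; otherwise all
products are computed matrix-free as ``X1'(X2 v)`` at O(n(p1+p2)) cost, with
rank-one deflation corrections applied on the fly.  Further component pairs
are extracted by deflating ``Z`` with the already-found rank-one terms.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateDirectionError",
    "ViewMatrix",
    "SparsityParams",
    "CanonicalComponent",
    "DeflationState",
    "CrossCovOperator",
    "standardize_columns",
    "soft_threshold",
    "l1_project",
    "scca_rank1",
    "fit_scca",
    "canonical_correlation",
    "inflate_weights",
]

#: above this many entries the explicit cross-product matrix is never formed
DENSE_CROSSPRODUCT_LIMIT = 1_000_000

_ZERO_SD = 1e-12


class DegenerateDirectionError(ValueError):
    """No admissible direction: the projection input is zero (or has no
    positive entry in nonnegative mode)."""


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class ViewMatrix:
    """One view's n x p feature matrix plus feature provenance.

    ``retained_idx`` maps the (possibly reduced) columns back to positions in
    the original input matrix: zero-variance columns are dropped at
    standardization and weight vectors are re-inflated with explicit zeros at
    those positions (see :func:`inflate_weights`).
    """

    data: np.ndarray
    feature_ids: np.ndarray
    standardized: bool = False
    retained_idx: np.ndarray | None = None
    dropped_ids: np.ndarray | None = None
    n_original: int | None = None

    def __post_init__(self) -> None:
        data = np.ascontiguousarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("view data must be a 2-D matrix")
        if data.shape[0] < 2 or data.shape[1] < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        if not np.all(np.isfinite(data)):
            raise ValueError("view data contains non-finite entries")
        fid = np.asarray(self.feature_ids)
        if fid.shape != (data.shape[1],):
            raise ValueError("feature_ids length must match number of columns")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "feature_ids", fid)
        if self.retained_idx is None:
            object.__setattr__(self, "retained_idx", np.arange(data.shape[1]))
        if self.n_original is None:
            object.__setattr__(self, "n_original", data.shape[1])
        if self.dropped_ids is None:
            object.__setattr__(self, "dropped_ids", fid[:0])

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    def permute_rows(self, perm: np.ndarray) -> "ViewMatrix":
        """Return a copy with rows reordered (column moments unchanged)."""
        return replace(self, data=self.data[np.asarray(perm)])


@dataclass(frozen=True)
class SparsityParams:
    """Per-view sparsity levels and solver controls.

    ``c1``, ``c2`` are fractional L1 budgets in (0, 1]: the effective bound on
    view k is ``c_k * sqrt(p_k)``, so the same c is comparable across views of
    different dimension.  ``c = 1`` allows the densest solution the L2 ball
    admits; smaller values force more weights to exactly zero.
    """

    c1: float
    c2: float
    nonnegative: bool = True
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        for name, c in (("c1", self.c1), ("c2", self.c2)):
            if not (0.0 < c <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {c}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class CanonicalComponent:
    """One extracted pair of canonical vectors.

    ``q`` is the Pearson correlation of the canonical variables ``X1 u`` and
    ``X2 v`` (the quantity tested and reported); ``q_raw`` is the bilinear
    score ``u' Z_def v`` used for deflation.  ``degenerate`` marks components
    where no admissible direction existed (zero vectors, q = 0) or where a
    canonical variable had zero variance.
    """

    u: np.ndarray
    v: np.ndarray
    q: float
    q_raw: float
    index: int
    n_nonzero_u: int
    n_nonzero_v: int
    converged: bool = True
    degenerate: bool = False


@dataclass
class DeflationState:
    """Accumulated rank-one corrections ``(q_raw, u, v)``.

    Supports matrix-free products with the deflated cross-product matrix:
    ``Z_def w = X1'(X2 w) - sum_i q_i u_i (v_i' w)`` — the explicit deflated
    matrix is never required.
    """

    components: list[tuple[float, np.ndarray, np.ndarray]] = field(default_factory=list)

    def append(self, q_raw: float, u: np.ndarray, v: np.ndarray) -> None:
        self.components.append(
            (float(q_raw), np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64))
        )

    def __len__(self) -> int:
        return len(self.components)


class CrossCovOperator:
    """Products with the (deflated) cross-product matrix ``Z = X1' X2``.

    When ``p1 * p2`` is small the matrix is cached densely and deflation is a
    rank-one subtraction; otherwise products stay matrix-free.  Both routes
    are numerically interchangeable (tested to 1e-8) — the choice is purely
    a memory/speed trade-off.
    """

    def __init__(
        self,
        X1: np.ndarray,
        X2: np.ndarray,
        state: DeflationState | None = None,
        materialize: bool | None = None,
    ) -> None:
        self.X1 = np.asarray(X1, dtype=np.float64)
        self.X2 = np.asarray(X2, dtype=np.float64)
        if self.X1.shape[0] != self.X2.shape[0]:
            raise ValueError("views must have the same number of rows")
        self.p1 = self.X1.shape[1]
        self.p2 = self.X2.shape[1]
        if materialize is None:
            materialize = self.p1 * self.p2 <= DENSE_CROSSPRODUCT_LIMIT
        self.dense: np.ndarray | None = None
        if materialize:
            self.dense = self.X1.T @ self.X2
        self.components: list[tuple[float, np.ndarray, np.ndarray]] = []
        if state is not None:
            for q_raw, u, v in state.components:
                self.deflate(q_raw, u, v)

    def deflate(self, q_raw: float, u: np.ndarray, v: np.ndarray) -> None:
        u = np.asarray(u, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        self.components.append((float(q_raw), u, v))
        if self.dense is not None:
            self.dense -= float(q_raw) * np.outer(u, v)

    def matvec(self, w: np.ndarray) -> np.ndarray:
        """``Z_def @ w`` for a length-p2 vector ``w``."""
        if self.dense is not None:
            return self.dense @ w
        out = self.X1.T @ (self.X2 @ w)
        for q_raw, u, v in self.components:
            out -= q_raw * (v @ w) * u
        return out

    def rmatvec(self, w: np.ndarray) -> np.ndarray:
        """``Z_def.T @ w`` for a length-p1 vector ``w``."""
        if self.dense is not None:
            return self.dense.T @ w
        out = self.X2.T @ (self.X1 @ w)
        for q_raw, u, v in self.components:
            out -= q_raw * (u @ w) * v
        return out


# ---------------------------------------------------------------------------
# elementary operations


def standardize_columns(X: np.ndarray, feature_ids: np.ndarray | None = None) -> ViewMatrix:
    """Center and scale each column to mean 0, sample sd 1 (ddof = 1).

    Zero-variance columns carry no information and break scaling; they are
    dropped, their identities recorded on the returned view, and weight maps
    later re-inflate them as explicit zeros.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite entries")
    if feature_ids is None:
        feature_ids = np.arange(X.shape[1])
    feature_ids = np.asarray(feature_ids)
    if feature_ids.shape != (X.shape[1],):
        raise ValueError("feature_ids length must match number of columns")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > _ZERO_SD
    if not keep.any():
        raise ValueError("no informative features: all columns have zero variance")
    dropped = feature_ids[~keep]
    if dropped.size:
        logger.info("dropping %d zero-variance columns: %s", dropped.size, dropped[:20])
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return ViewMatrix(
        data=Z,
        feature_ids=feature_ids[keep],
        standardized=True,
        retained_idx=np.flatnonzero(keep),
        dropped_ids=dropped,
        n_original=X.shape[1],
    )


def soft_threshold(a: np.ndarray, delta: float, nonnegative: bool = False) -> np.ndarray:
    """Shrink-toward-zero operator implementing the L1 penalty.

    Signed mode: ``sign(a_i) * max(|a_i| - delta, 0)``.  Nonnegative mode:
    ``max(a_i - delta, 0)`` (negative entries are zeroed even at delta = 0).
    """
    a = np.asarray(a, dtype=np.float64)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if nonnegative:
        return np.maximum(a - delta, 0.0)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _basis_vector(a: np.ndarray, order: np.ndarray, nonnegative: bool) -> np.ndarray:
    # tie-break: lowest feature index among the maximal magnitudes survives
    w = np.zeros_like(a)
    i = order[0]
    w[i] = 1.0 if (nonnegative or a[i] >= 0) else -1.0
    return w


def _bisect_delta(a: np.ndarray, s: float, nonnegative: bool,
                  lo: float, hi: float, tol: float = 1e-8, max_steps: int = 100) -> float:
    # classic fallback: the L1/L2 ratio of the thresholded vector decreases in delta
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        w = soft_threshold(a, mid, nonnegative)
        n2 = math.sqrt(float(w @ w))
        if n2 == 0.0:
            hi = mid
            continue
        ratio = float(np.abs(w).sum()) / n2
        if abs(ratio - s) < tol:
            return mid
        if ratio > s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def l1_project(a: np.ndarray, s: float, nonnegative: bool = False) -> np.ndarray:
    """Project onto the intersection of the unit L2 sphere and L1 ball of
    radius ``s``: returns ``w = S(a, d*) / ||S(a, d*)||_2`` with the smallest
    threshold ``d*`` such that ``||w||_1 <= s``.

    ``s >= 1`` is required (a unit-L2 vector always has L1 norm >= 1).  The
    threshold is located exactly by solving the quadratic for ``d`` inside the
    sorted-magnitude interval where the L1/L2 ratio crosses ``s``; exact ties
    at the maximal magnitude that make the constraint unreachable collapse to
    the unit basis vector of the lowest-index maximal entry.

    Raises :class:`DegenerateDirectionError` when ``a`` is zero (or has no
    positive entry in nonnegative mode).
    """
    a = np.asarray(a, dtype=np.float64)
    if s < 1.0 - 1e-12:
        raise ValueError(f"L1 bound s must be >= 1, got {s}")
    if nonnegative:
        a = np.maximum(a, 0.0)
    m = np.abs(a)
    norm2 = math.sqrt(float(a @ a))
    if norm2 <= 0.0:
        raise DegenerateDirectionError(
            "no admissible direction (zero, or all-nonpositive in nonnegative mode)"
        )
    w = a / norm2
    if float(np.abs(w).sum()) <= s + 1e-12:
        return w

    # thresholding needed: find the support-size interval where the
    # L1/L2 ratio of S(a, d) equals s, then solve for d in closed form
    order = np.argsort(-m, kind="stable")
    ms = m[order]
    p = ms.size
    cs1 = np.cumsum(ms)
    cs2 = np.cumsum(ms * ms)
    j = np.arange(1, p)
    l1 = cs1[j - 1] - j * ms[j]
    l2sq = cs2[j - 1] - 2.0 * ms[j] * cs1[j - 1] + j * ms[j] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(l2sq > 0.0, l1 / np.sqrt(np.maximum(l2sq, 0.0)), -np.inf)
    # ratio is nondecreasing in j (support size); the full-support ratio > s
    idx = int(np.searchsorted(ratio, s, side="left"))
    k = idx + 1  # support size; d* lies in [ms[k], ms[k-1])
    S1 = float(cs1[k - 1])
    S2 = float(cs2[k - 1])
    kk = float(k)
    s2 = s * s
    inner = kk * S2 - S1 * S1
    denom = kk - s2
    delta = None
    if denom > 1e-14 and inner >= 0.0:
        root = s * math.sqrt(inner / denom)
        cand = (S1 - root) / kk
        lo = float(ms[k]) if k < p else 0.0
        hi = float(ms[k - 1])
        if lo - 1e-12 <= cand <= hi + 1e-12:
            delta = min(max(cand, lo), hi)
    if delta is None:
        # degenerate interval (ties, or s^2 == k): fall back to bisection
        delta = _bisect_delta(a, s, nonnegative, lo=0.0, hi=float(ms[0]))
    out = soft_threshold(a, delta, nonnegative)
    n2 = math.sqrt(float(out @ out))
    if n2 <= 0.0 or float(np.abs(out).sum()) / n2 > s + 1e-6:
        # unreachable via soft-thresholding (tied maxima with s < sqrt(#ties))
        return _basis_vector(a, order, nonnegative)
    return out / n2


# ---------------------------------------------------------------------------
# rank-one solver and deflation loop


def _power_init(op: CrossCovOperator, seed: int = 0,
                n_iter: int = 30, tol: float = 1e-7) -> np.ndarray | None:
    """Leading right-singular direction of the deflated cross-product matrix,
    by power iteration from a seeded random start.  Returns None when the
    operator is (numerically) zero."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(op.p2)
    v /= math.sqrt(float(v @ v))
    for _ in range(n_iter):
        u = op.matvec(v)
        nv = op.rmatvec(u)
        nn = math.sqrt(float(nv @ nv))
        if nn <= 1e-300:
            return None
        nv /= nn
        if float(np.max(np.abs(nv - v))) < tol:
            v = nv
            break
        v = nv
    # fix orientation: largest-magnitude entry positive
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v


def _effective_bound(c: float, p: int) -> float:
    s = c * math.sqrt(p)
    if s < 1.0:
        warnings.warn(
            f"effective L1 bound c*sqrt(p) = {s:.3g} < 1 is infeasible; clamping to 1",
            RuntimeWarning,
            stacklevel=3,
        )
        s = 1.0
    return s


def _zero_component(p1: int, p2: int, index: int) -> CanonicalComponent:
    return CanonicalComponent(
        u=np.zeros(p1),
        v=np.zeros(p2),
        q=0.0,
        q_raw=0.0,
        index=index,
        n_nonzero_u=0,
        n_nonzero_v=0,
        converged=False,
        degenerate=True,
    )


def _check_views(X1: ViewMatrix, X2: ViewMatrix) -> None:
    if not (X1.standardized and X2.standardized):
        raise ValueError("views must be standardized (use standardize_columns)")
    if X1.n != X2.n:
        raise ValueError("views must have the same number of samples")


def scca_rank1(
    X1: ViewMatrix,
    X2: ViewMatrix,
    params: SparsityParams,
    state: DeflationState | None = None,
    init: np.ndarray | str | int = "svd",
    *,
    init_seed: int = 0,
    operator: CrossCovOperator | None = None,
    materialize: bool | None = None,
    objective_trace: list | None = None,
) -> CanonicalComponent:
    """Extract one pair of sparse canonical vectors by alternating
    L1-constrained projections of deflated cross-product products.

    ``init``: "svd" (power-iteration start, seeded by ``init_seed``), an
    explicit start vector for v, or an integer seed for a random start.  The
    objective ``u' Z_def v`` is non-decreasing across iterations; the loop
    stops when the max elementwise change in both u and v falls below
    ``params.tol`` or after ``params.max_iter`` sweeps (``converged=False``).
    Degenerate instances (no admissible direction) return a flagged zero
    component rather than raising, so permutation grids can score over-sparse
    settings without crashing.
    """
    _check_views(X1, X2)
    p1, p2 = X1.p, X2.p
    s1 = _effective_bound(params.c1, p1)
    s2 = _effective_bound(params.c2, p2)
    op = operator
    if op is None:
        op = CrossCovOperator(X1.data, X2.data, state=state, materialize=materialize)
    index = len(op.components) + 1
    nonneg = params.nonnegative

    if isinstance(init, np.ndarray):
        v = np.asarray(init, dtype=np.float64).copy()
        nn = math.sqrt(float(v @ v))
        if nn <= 0:
            raise ValueError("init vector must be nonzero")
        v /= nn
    elif isinstance(init, str):
        if init != "svd":
            raise ValueError(f"unknown init {init!r}")
        v = _power_init(op, seed=init_seed)
        if v is None:
            return _zero_component(p1, p2, index)
    elif isinstance(init, (int, np.integer)):
        rng = np.random.default_rng(int(init))
        v = rng.standard_normal(p2)
        v /= math.sqrt(float(v @ v))
    else:
        raise ValueError("init must be a vector, 'svd', or an integer seed")

    u = np.zeros(p1)
    converged = False
    for it in range(params.max_iter):
        u_old, v_old = u, v
        try:
            u = l1_project(op.matvec(v), s1, nonneg)
        except DegenerateDirectionError:
            if it == 0 and nonneg:
                # power-iteration sign is arbitrary; the flipped start may be admissible
                try:
                    v = -v
                    u = l1_project(op.matvec(v), s1, nonneg)
                except DegenerateDirectionError:
                    return _zero_component(p1, p2, index)
            else:
                return _zero_component(p1, p2, index)
        try:
            b = op.rmatvec(u)
            v = l1_project(b, s2, nonneg)
        except DegenerateDirectionError:
            return _zero_component(p1, p2, index)
        if objective_trace is not None:
            # u'Zv falls out of the v-update product for free
            objective_trace.append(float(b @ v))
        if it > 0 and max(
            float(np.max(np.abs(u - u_old))), float(np.max(np.abs(v - v_old)))
        ) < params.tol:
            converged = True
            break

    q_raw = float(u @ op.matvec(v))
    q = canonical_correlation(X1, u, X2, v)
    degenerate = False
    if not np.isfinite(q):
        # zero-variance canonical variable: flagged, scored as q = 0
        q = 0.0
        degenerate = True
    return CanonicalComponent(
        u=u,
        v=v,
        q=q,
        q_raw=q_raw,
        index=index,
        n_nonzero_u=int(np.count_nonzero(u)),
        n_nonzero_v=int(np.count_nonzero(v)),
        converged=converged,
        degenerate=degenerate,
    )


def fit_scca(
    X1: ViewMatrix,
    X2: ViewMatrix,
    params: SparsityParams,
    n_components: int = 1,
    *,
    init_seed: int = 0,
    materialize: bool | None = None,
) -> tuple[list[CanonicalComponent], DeflationState]:
    """Extract ``n_components`` canonical-vector pairs by repeated rank-one
    fits with deflation of the cross-product matrix between extractions.

    Components come back in extraction order; they are not orthogonal (the L1
    and nonnegativity constraints preclude that).  Extraction stops early, with
    a warning, at the first degenerate component.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    _check_views(X1, X2)
    state = DeflationState()
    op = CrossCovOperator(X1.data, X2.data, materialize=materialize)
    components: list[CanonicalComponent] = []
    for i in range(n_components):
        comp = scca_rank1(X1, X2, params, operator=op, init_seed=init_seed)
        if comp.degenerate:
            warnings.warn(
                f"component {i + 1} is degenerate; stopping after {i} components",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        components.append(comp)
        state.append(comp.q_raw, comp.u, comp.v)
        op.deflate(comp.q_raw, comp.u, comp.v)
    return components, state


def canonical_correlation(
    X1: ViewMatrix | np.ndarray,
    u: np.ndarray,
    X2: ViewMatrix | np.ndarray,
    v: np.ndarray,
) -> float:
    """Pearson correlation of the canonical variables ``X1 u`` and ``X2 v``.

    Returns NaN when either canonical variable has zero variance; callers
    treat that as q = 0 with a degeneracy flag.
    """
    A = X1.data if isinstance(X1, ViewMatrix) else np.asarray(X1, dtype=np.float64)
    B = X2.data if isinstance(X2, ViewMatrix) else np.asarray(X2, dtype=np.float64)
    a = A @ np.asarray(u, dtype=np.float64)
    b = B @ np.asarray(v, dtype=np.float64)
    a = a - a.mean()
    b = b - b.mean()
    na = math.sqrt(float(a @ a))
    nb = math.sqrt(float(b @ b))
    if na <= _ZERO_SD or nb <= _ZERO_SD:
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def inflate_weights(w: np.ndarray, view: ViewMatrix) -> np.ndarray:
    """Re-inflate a weight vector over retained columns to the original
    feature space, with explicit zeros at dropped (zero-variance) positions."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (view.p,):
        raise ValueError("weight length must match the view's retained columns")
    out = np.zeros(view.n_original)
    out[view.retained_idx] = w
    return out
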