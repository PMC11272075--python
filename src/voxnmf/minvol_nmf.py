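"""Minimum-volume NMF for nonnegative subject-by-voxel matrices.

Model
-----
``X ≈ L @ D`` with ``L >= 0`` (subjects x rank, each row on the capped
simplex ``sum(l) <= 1``) and ``D >= 0`` (rank x voxels). The fitted
objective is

    ``|| X - L D ||_F^2  +  lam * logdet(D D^T + delta * I)``

where the log-determinant term shrinks the volume spanned by the
components, giving identifiability even when the dictionary is
rank-deficient. The capped-simplex constraint on load rows removes the
diagonal rescaling ambiguity.

``lam`` is derived from the config's relative volume weight so the penalty
is scale-free across datasets:

    ``lam = vol_weight * ||X - L0 D0||_F^2 / max(1, |logdet(D0 D0^T + delta I)|)``

Updates alternate a multiplicative dictionary step (with the logdet
gradient split into positive/negative parts and a backtracking safeguard)
and an exact-to-tolerance capped-simplex nonnegative least-squares step for
the loads, so the recorded objective trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from voxnmf.errors import ArgumentError, DimensionError, DomainError, NumericalError
from voxnmf.imaging_io import MaskedGrid, VoxelMatrix

_FLOOR = 1e-12


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of a minimum-volume NMF fit.

    ``vol_weight`` is a *relative* weight: the absolute penalty multiplier
    is computed from the initialization (see module docstring).
    """

    rank: int
    vol_weight: float = 0.01
    logdet_ridge: float = 1.0
    max_iter: int = 500
    rel_tol: float = 1e-6
    seed: int = 0
    init: str = "nndsvd"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ArgumentError(f"rank must be >= 1, got {self.rank}")
        if self.vol_weight < 0:
            raise ArgumentError("vol_weight must be nonnegative")
        if self.logdet_ridge <= 0:
            raise ArgumentError("logdet_ridge must be positive")
        if self.rel_tol <= 0:
            raise ArgumentError("rel_tol must be positive")
        if self.max_iter < 1:
            raise ArgumentError("max_iter must be >= 1")
        if self.init not in ("nndsvd", "random"):
            raise ArgumentError(f"init must be 'nndsvd' or 'random', got {self.init!r}")

    def replace(self, **kwargs) -> "NMFConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class NMFModel:
    """A fitted factorization: dictionary, loads, and convergence trace."""

    config: NMFConfig
    dictionary: np.ndarray  # (rank, voxels)
    loads: np.ndarray  # (subjects, rank)
    objective_trace: np.ndarray
    converged: bool
    vol_weight_abs: float
    subject_ids: list = field(default_factory=list)
    grid: Optional[MaskedGrid] = None

    @property
    def rank(self) -> int:
        return self.dictionary.shape[0]


@dataclass(frozen=True)
class FitSummary:
    reconstruction_mae: float
    final_objective: float
    iterations_run: int


# ---------------------------------------------------------------------------
# objective and error
# ---------------------------------------------------------------------------


def _check_conforming(X: np.ndarray, L: np.ndarray, D: np.ndarray) -> None:
    if L.shape[1] != D.shape[0]:
        raise DimensionError(f"L has {L.shape[1]} components but D has {D.shape[0]} rows")
    if X.shape != (L.shape[0], D.shape[1]):
        raise DimensionError(
            f"X shape {X.shape} does not conform with L {L.shape} and D {D.shape}"
        )


def objective_value(
    X: np.ndarray, L: np.ndarray, D: np.ndarray, lam: float, delta: float
) -> float:
    """``||X - L D||_F^2 + lam * logdet(D D^T + delta I)``."""
    X, L, D = np.asarray(X, float), np.asarray(L, float), np.asarray(D, float)
    _check_conforming(X, L, D)
    if delta <= 0:
        raise ArgumentError("delta must be positive")
    resid = X - L @ D
    data_term = float(np.sum(resid * resid))
    gram = D @ D.T + delta * np.eye(D.shape[0])
    sign, logdet = np.linalg.slogdet(gram)
    if sign <= 0:  # impossible for delta > 0, but fail loudly
        raise NumericalError("non-positive-definite dictionary Gram matrix")
    return data_term + lam * float(logdet)


def reconstruction_mae(X: np.ndarray, L: np.ndarray, D: np.ndarray) -> float:
    """Mean absolute entrywise reconstruction error of ``L @ D`` against X."""
    X, L, D = np.asarray(X, float), np.asarray(L, float), np.asarray(D, float)
    _check_conforming(X, L, D)
    return float(np.mean(np.abs(X - L @ D)))


# ---------------------------------------------------------------------------
# capped-simplex projection and constrained least squares
# ---------------------------------------------------------------------------


def project_capped_simplex(V: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto ``{x >= 0, sum(x) <= 1}``.

    Clip negatives; rows whose clipped sum exceeds 1 are projected onto the
    probability simplex by the sort-based algorithm.
    """
    V = np.atleast_2d(np.asarray(V, float))
    X = np.clip(V, 0.0, None)
    over = X.sum(axis=1) > 1.0
    if np.any(over):
        W = V[over]
        r = W.shape[1]
        U = np.sort(W, axis=1)[:, ::-1]
        css = np.cumsum(U, axis=1) - 1.0
        ks = np.arange(1, r + 1)
        cond = U - css / ks > 0
        rho = cond.sum(axis=1)
        theta = css[np.arange(W.shape[0]), rho - 1] / rho
        X[over] = np.clip(W - theta[:, None], 0.0, None)
    return X


def solve_capped_nnls(
    G: np.ndarray,
    H: np.ndarray,
    L_init: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimize ``sum_i l_i G l_i' - 2 l_i h_i`` rows on the capped simplex.

    ``G = D D^T`` (rank x rank), ``H = X D^T`` (subjects x rank). Solved for
    all rows simultaneously with accelerated projected gradient (FISTA with
    gradient restart) and a keep-the-better-point safeguard, so the returned
    rows never have a larger subproblem objective than ``L_init``.
    """
    G = np.asarray(G, float)
    H = np.atleast_2d(np.asarray(H, float))
    r = G.shape[0]
    if L_init is None:
        L_init = np.zeros_like(H)
    L0 = project_capped_simplex(L_init)
    lip = float(np.linalg.eigvalsh(G)[-1])
    if lip <= 0:  # degenerate dictionary: any feasible point is optimal
        return L0
    step = 1.0 / lip
    L = L0.copy()
    Y = L.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = Y @ G - H
        L_new = project_capped_simplex(Y - step * grad)
        diff = L_new - L
        # gradient restart keeps FISTA stable on ill-conditioned G
        if np.sum(grad * diff) > 0:
            Y = L_new.copy()
            t = 1.0
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            Y = L_new + ((t - 1.0) / t_new) * diff
            t = t_new
        delta = float(np.max(np.abs(diff))) if diff.size else 0.0
        L = L_new
        if delta <= tol * max(1.0, float(np.max(np.abs(L)))):
            break

    def rowwise_obj(M: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", M, G, M) - 2.0 * np.einsum("ij,ij->i", M, H)

    worse = rowwise_obj(L) > rowwise_obj(L0)
    if np.any(worse):
        L[worse] = L0[worse]
    return L


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _nndsvd(X: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD init (positive-section heuristic)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, v = X.shape
    W = np.zeros((n, rank))
    Ht = np.zeros((rank, v))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    Ht[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, rank):
        u, vvec = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(vvec, 0, None), np.clip(-vvec, 0, None)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            norm = n_up * n_vp
            if norm > 0:
                W[:, j] = np.sqrt(S[j] * norm) * up / n_up
                Ht[j] = np.sqrt(S[j] * norm) * vp / n_vp
        else:
            norm = n_un * n_vn
            if norm > 0:
                W[:, j] = np.sqrt(S[j] * norm) * un / n_un
                Ht[j] = np.sqrt(S[j] * norm) * vn / n_vn
    return W, Ht


def init_factors(X: np.ndarray, config: NMFConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic nonnegative initialization with capped-simplex load rows.

    The per-component scale is moved into the dictionary so that the largest
    load row sum equals 1 while ``L0 @ D0`` is preserved.
    """
    X = np.asarray(X, float)
    n, v = X.shape
    r = config.rank
    if r > min(n, v):
        raise ArgumentError(f"rank {r} exceeds min(n, v) = {min(n, v)}")
    if config.init == "nndsvd":
        L0, D0 = _nndsvd(X, r)
        # dead components (all-zero SVD sections) get a small uniform seed
        rng = np.random.default_rng(config.seed)
        for j in range(r):
            if not L0[:, j].any() or not D0[j].any():
                L0[:, j] = rng.uniform(0.0, 1.0, n) * X.mean() * 1e-2
                D0[j] = rng.uniform(0.0, 1.0, v)
    else:
        rng = np.random.default_rng(config.seed)
        L0 = rng.gamma(shape=2.0, scale=1.0, size=(n, r))
        L0 = 0.8 * L0 / L0.sum(axis=1, keepdims=True)
        scale = np.sqrt(max(X.mean(), _FLOOR))
        D0 = rng.gamma(shape=2.0, scale=scale, size=(r, v))
    row_sums = L0.sum(axis=1)
    c = max(float(row_sums.max()), _FLOOR)
    if c > 1.0:
        L0 = L0 / c
        D0 = D0 * c
    return L0, np.clip(D0, 0.0, None)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, VoxelMatrix) else np.asarray(X, float)


def _update_dictionary(
    X: np.ndarray,
    L: np.ndarray,
    D: np.ndarray,
    lam: float,
    delta: float,
    obj_prev: float,
    inner: int = 3,
) -> np.ndarray:
    """Majorize-minimize D step.

    The concave logdet term is majorized by its tangent at the current D,
    ``logdet(D D' + delta I) <= const + tr(Y D D')`` with
    ``Y = (D D' + delta I)^-1``, turning the subproblem into a convex
    quadratic with coefficient matrix ``L'L + lam Y``, minimized by
    component-wise HALS sweeps over the nonnegative orthant. Each sweep
    decreases the majorizer and hence the true objective; a backtracking
    safeguard guards against floating-point slack.
    """
    r = D.shape[0]
    LtX = L.T @ X
    Y = np.linalg.inv(D @ D.T + delta * np.eye(r))
    M = L.T @ L + lam * Y
    D_cand = D.copy()
    for _ in range(inner):
        for j in range(r):
            num = LtX[j] - M[j] @ D_cand + M[j, j] * D_cand[j]
            D_cand[j] = np.clip(num / max(M[j, j], _FLOOR), 0.0, None)
    t = 1.0
    for _ in range(25):
        D_try = D + t * (D_cand - D)
        if objective_value(X, L, D_try, lam, delta) <= obj_prev + 1e-12 * max(1.0, obj_prev):
            return D_try
        t *= 0.5
    return D


def fit_minvol_nmf(X, config: NMFConfig) -> tuple[NMFModel, FitSummary]:
    """Alternate dictionary and load updates until the relative objective
    change drops below ``config.rel_tol`` or ``config.max_iter`` is reached.
    """
    Xv = _values(X)
    if Xv.size and Xv.min() < 0:
        raise DomainError("input matrix must be nonnegative")
    n, v = Xv.shape
    if config.rank > min(n, v):
        raise ArgumentError(f"rank {config.rank} exceeds min(n, v) = {min(n, v)}")
    delta = config.logdet_ridge
    L, D = init_factors(Xv, config)

    resid0 = float(np.sum((Xv - L @ D) ** 2))
    sign, logdet0 = np.linalg.slogdet(D @ D.T + delta * np.eye(config.rank))
    lam = config.vol_weight * resid0 / max(1.0, abs(float(logdet0)))

    obj = objective_value(Xv, L, D, lam, delta)
    trace = [obj]
    converged = False
    for it in range(config.max_iter):
        D = _update_dictionary(Xv, L, D, lam, delta, trace[-1])
        G = D @ D.T
        H = Xv @ D.T
        # few inner iterations per outer step: the safeguard keeps the
        # subproblem objective non-increasing, full accuracy comes from the
        # final polish below
        L = solve_capped_nnls(G, H, L_init=L, max_iter=40, tol=1e-10)
        obj = objective_value(Xv, L, D, lam, delta)
        if not np.isfinite(obj):
            raise NumericalError(f"non-finite objective at iteration {it}")
        if __debug__:
            assert D.min() >= 0.0, f"negative dictionary entry at iteration {it}"
            assert L.min() >= 0.0, f"negative load at iteration {it}"
            assert L.sum(axis=1).max() <= 1.0 + 1e-9, f"load row off simplex at iteration {it}"
        trace.append(obj)
        if abs(trace[-2] - obj) <= config.rel_tol * max(abs(trace[-2]), _FLOOR):
            converged = True
            break

    # polish loads at the final dictionary
    L = solve_capped_nnls(D @ D.T, Xv @ D.T, L_init=L, max_iter=2000)
    trace.append(objective_value(Xv, L, D, lam, delta))

    model = NMFModel(
        config=config,
        dictionary=D,
        loads=L,
        objective_trace=np.asarray(trace),
        converged=converged,
        vol_weight_abs=lam,
        subject_ids=list(X.subject_ids) if isinstance(X, VoxelMatrix) else [],
        grid=X.grid if isinstance(X, VoxelMatrix) else None,
    )
    summary = FitSummary(
        reconstruction_mae=reconstruction_mae(Xv, L, D),
        final_objective=float(trace[-1]),
        iterations_run=len(trace) - 1,
    )
    return model, summary


def project_loads(X_new, D: np.ndarray) -> np.ndarray:
    """Loads for new subjects on a fixed dictionary.

    Solves, per subject, the same capped-simplex nonnegative least-squares
    subproblem used for the load update during fitting.
    """
    Xv = _values(X_new)
    D = np.asarray(D, float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != D.shape[1]:
        raise DimensionError(
            f"X_new has {Xv.shape[1]} columns but dictionary has {D.shape[1]}"
        )
    if Xv.size and Xv.min() < 0:
        raise DomainError("input matrix must be nonnegative")
    return solve_capped_nnls(D @ D.T, Xv @ D.T, max_iter=5000)
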