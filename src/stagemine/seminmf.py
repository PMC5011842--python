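"""Semi-supervised non-negative matrix tri-factorization.

The row-normalized note x keyword matrix X (L x K) is factorized as
X ~ F H G^T with F (L x S), H (S x S), G (K x S) all non-negative.  Partial
supervision enters through one-hot label matrices F0 (expert-labeled notes)
and G0 (keywords uniquely selected by one stage) with diagonal indicator
masks C0, C1, penalized in the objective

    J = ||X - F H G^T||_F^2
        + alpha * trace((F - F0)^T C0 (F - F0))
        + beta  * trace((G - G0)^T C1 (G - G0)).

J is minimized by multiplicative updates applied in the order F, H, G, each
using the most recent factors.  The default "monotone" rule uses the
auxiliary-function denominators

    F <- F * (X G H^T + a C0 F0) / (F (H G^T G H^T) + a C0 F)
    H <- H * (F^T X G)           / (F^T F H G^T G)
    G <- G * (X^T F H + b C1 G0) / (G (H^T F^T F H) + b C1 G)

for which the objective is provably non-increasing (the same argument as for
classical least-squares NMF: each denominator comes from a quadratic upper
bound with positive-semidefinite curvature).  An alternative
``update_rule="projection"`` substitutes the orthogonality-style denominators
F F^T X G H^T + a C0 F and G G^T X^T F H + b C1 G; that variant is not
monotone when orthogonality of F and G is not enforced (and it is not
enforced here) and is provided for comparison only.

At a stationary point the KKT complementarity condition holds entrywise:
(dJ/dF)_ik * F_ik = 0 with dJ/dF = -2 X G H^T + 2 F H G^T G H^T
+ 2 alpha C0 (F - F0); the maximum absolute violation is reported as a
convergence diagnostic.  Rows of F and G are normalized to probability
vectors once, after convergence — the updates do not preserve
row-stochasticity, and renormalizing inside the loop would forfeit the
monotonicity guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LabelConstraints",
    "FactorizationResult",
    "NumericalError",
    "objective_value",
    "update_step",
    "fit_semi_nmf",
    "kkt_residual",
    "save_result",
    "load_result",
]

try:  # compiled fast path for the iteration loop; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


#: Additive stabilizer for update denominators.
EPSILON = 1e-12
#: Default relative-objective-change stopping tolerance and iteration cap.
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


class NumericalError(RuntimeError):
    """A factor became NaN/Inf during iteration."""


@dataclass
class LabelConstraints:
    """Partial labels F0 (L x S), G0 (K x S) and their penalty weights.

    Every non-zero row of F0/G0 must be one-hot.  The diagonal masks C0, C1
    are derived (``c0[i] = 1`` iff row i of F0 is non-zero) and stored as
    vectors.
    """

    F0: np.ndarray
    G0: np.ndarray
    alpha: float = 1.0
    beta: float = 1.0
    c0: np.ndarray = field(init=False)
    c1: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.F0 = np.asarray(self.F0, dtype=float)
        self.G0 = np.asarray(self.G0, dtype=float)
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.F0.ndim != 2 or self.G0.ndim != 2:
            raise ValueError("F0 and G0 must be 2-D")
        if self.F0.shape[1] != self.G0.shape[1]:
            raise ValueError("F0 and G0 must have the same number of stages")
        for name, M in (("F0", self.F0), ("G0", self.G0)):
            nonzero = M != 0
            if not np.all((M == 0) | (M == 1)) or np.any(nonzero.sum(axis=1) > 1):
                raise ValueError(f"non-zero rows of {name} must be one-hot 0/1")
        self.c0 = (self.F0.sum(axis=1) > 0).astype(float)
        self.c1 = (self.G0.sum(axis=1) > 0).astype(float)

    @property
    def n_stages(self) -> int:
        return self.F0.shape[1]

    @classmethod
    def from_labels(
        cls,
        note_labels: Sequence[int | None],
        keyword_stages: Sequence[int | None],
        n_stages: int,
        alpha: float = 1.0,
        beta: float = 1.0,
    ) -> "LabelConstraints":
        """Build one-hot F0/G0 from per-note and per-keyword stage ids (1-based)."""
        F0 = np.zeros((len(note_labels), n_stages))
        for i, lab in enumerate(note_labels):
            if lab is not None:
                if not 1 <= lab <= n_stages:
                    raise ValueError(f"note label {lab} outside 1..{n_stages}")
                F0[i, lab - 1] = 1.0
        G0 = np.zeros((len(keyword_stages), n_stages))
        for i, lab in enumerate(keyword_stages):
            if lab is not None:
                if not 1 <= lab <= n_stages:
                    raise ValueError(f"keyword label {lab} outside 1..{n_stages}")
                G0[i, lab - 1] = 1.0
        return cls(F0=F0, G0=G0, alpha=alpha, beta=beta)


@dataclass
class FactorizationResult:
    """Converged factors with probability-normalized rows and diagnostics.

    ``F``/``G`` rows sum to 1 (all-zero rows become uniform); ``F_raw``,
    ``G_raw``, ``H`` are the un-normalized converged factors on which the
    KKT residual is evaluated.  ``objective_trace[t]`` is the objective after
    iteration t+1; ``initial_objective`` the value at the starting point.
    """

    F: np.ndarray
    H: np.ndarray
    G: np.ndarray
    F_raw: np.ndarray
    G_raw: np.ndarray
    objective_trace: np.ndarray
    initial_objective: float
    iterations: int
    converged: bool
    kkt_residual_F: float
    seed: int

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _check_dims(X: np.ndarray, F: np.ndarray, H: np.ndarray, G: np.ndarray) -> None:
    L, K = X.shape
    S = H.shape[0]
    if F.shape != (L, S) or H.shape != (S, S) or G.shape != (K, S):
        raise ValueError(
            f"dimension mismatch: X{X.shape}, F{F.shape}, H{H.shape}, G{G.shape}"
        )


def objective_value(
    X: np.ndarray,
    F: np.ndarray,
    H: np.ndarray,
    G: np.ndarray,
    constraints: LabelConstraints,
) -> float:
    """Evaluate the penalized squared-Frobenius objective J."""
    _check_dims(X, F, H, G)
    R = X - F @ H @ G.T
    c0, c1 = constraints.c0, constraints.c1
    return float(
        (R * R).sum()
        + constraints.alpha * ((F - constraints.F0) ** 2 * c0[:, None]).sum()
        + constraints.beta * ((G - constraints.G0) ** 2 * c1[:, None]).sum()
    )


def _check_finite(name: str, M: np.ndarray, iteration: int) -> None:
    if not np.all(np.isfinite(M)):
        raise NumericalError(f"{name} became non-finite at iteration {iteration}")


def update_step(
    X: np.ndarray,
    F: np.ndarray,
    H: np.ndarray,
    G: np.ndarray,
    constraints: LabelConstraints,
    eps: float = EPSILON,
    update_rule: str = "monotone",
    iteration: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative update of F, then H, then G (latest factors used)."""
    if update_rule not in ("monotone", "projection"):
        raise ValueError(f"unknown update_rule {update_rule!r}")
    _check_dims(X, F, H, G)
    a, b = constraints.alpha, constraints.beta
    F0, G0 = constraints.F0, constraints.G0
    c0 = constraints.c0[:, None]
    c1 = constraints.c1[:, None]

    XGHt = X @ G @ H.T
    if update_rule == "monotone":
        denF = F @ (H @ (G.T @ G) @ H.T) + a * c0 * F
    else:
        denF = F @ (F.T @ XGHt) + a * c0 * F
    F = F * (XGHt + a * c0 * F0) / (denF + eps)
    _check_finite("F", F, iteration)

    GtG = G.T @ G
    H = H * (F.T @ X @ G) / (F.T @ F @ H @ GtG + eps)
    _check_finite("H", H, iteration)

    XtFH = X.T @ F @ H
    if update_rule == "monotone":
        denG = G @ (H.T @ (F.T @ F) @ H) + b * c1 * G
    else:
        denG = G @ (G.T @ XtFH) + b * c1 * G
    G = G * (XtFH + b * c1 * G0) / (denG + eps)
    _check_finite("G", G, iteration)
    return F, H, G


def kkt_residual(
    X: np.ndarray,
    F: np.ndarray,
    H: np.ndarray,
    G: np.ndarray,
    constraints: LabelConstraints,
) -> float:
    """Max entrywise violation of the complementarity condition for F.

    Returns max_ik |(dJ/dF)_ik * F_ik| evaluated on un-normalized factors;
    zero at any stationary point of the constrained problem.
    """
    _check_dims(X, F, H, G)
    grad = (
        -2.0 * X @ G @ H.T
        + 2.0 * F @ (H @ (G.T @ G) @ H.T)
        + 2.0 * constraints.alpha * constraints.c0[:, None] * (F - constraints.F0)
    )
    return float(np.abs(grad * F).max())


def _init_factors(
    X: np.ndarray, constraints: LabelConstraints, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strictly positive random init; labeled F rows blend 0.5 F0 + 0.5 random."""
    rng = np.random.default_rng(seed)
    L, K = X.shape
    S = constraints.n_stages
    F = rng.uniform(0.1, 1.1, size=(L, S))
    G = rng.uniform(0.1, 1.1, size=(K, S))
    H = np.eye(S) + 0.1
    labeled = constraints.c0 > 0
    F[labeled] = 0.5 * constraints.F0[labeled] + 0.5 * F[labeled]
    return F, H, G


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    """Row-normalize to sum 1; all-zero rows become uniform."""
    M = M.copy()
    sums = M.sum(axis=1)
    zero = sums <= 0
    M[~zero] /= sums[~zero, None]
    M[zero] = 1.0 / M.shape[1]
    return M


@_njit(cache=True, fastmath=True)
def _mm(A, B, out):  # out = A @ B
    n, k = A.shape
    m = B.shape[1]
    for i in range(n):
        for j in range(m):
            out[i, j] = 0.0
        for p in range(k):
            a = A[i, p]
            for j in range(m):
                out[i, j] += a * B[p, j]


@_njit(cache=True, fastmath=True)
def _mmT(A, B, out):  # out = A @ B.T
    n, k = A.shape
    m = B.shape[0]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for p in range(k):
                s += A[i, p] * B[j, p]
            out[i, j] = s


@_njit(cache=True, fastmath=True)
def _mTm(A, B, out):  # out = A.T @ B
    k, n = A.shape
    m = B.shape[1]
    for i in range(n):
        for j in range(m):
            out[i, j] = 0.0
    for p in range(k):
        for i in range(n):
            a = A[p, i]
            for j in range(m):
                out[i, j] += a * B[p, j]


@_njit(cache=True, fastmath=True)
def _monotone_loop(X, F, H, G, F0, G0, c0, c1, a, b, eps, max_iter, tol, obj0):
    """Compiled monotone-update iteration; same math as ``update_step``."""
    L, K = X.shape
    S = H.shape[0]
    X2 = 0.0
    for i in range(L):
        for j in range(K):
            X2 += X[i, j] * X[i, j]
    # work buffers, allocated once
    XG = np.empty((L, S))
    XGHt = np.empty((L, S))
    GtG = np.empty((S, S))
    SS1 = np.empty((S, S))
    SS2 = np.empty((S, S))
    SS3 = np.empty((S, S))
    denF = np.empty((L, S))
    FtF = np.empty((S, S))
    FtX = np.empty((S, K))
    XtFH = np.empty((K, S))
    denG = np.empty((K, S))
    trace = np.empty(max_iter)
    prev = obj0
    converged = False
    n_done = 0
    for it in range(max_iter):
        # F update
        _mm(X, G, XG)
        _mmT(XG, H, XGHt)
        _mTm(G, G, GtG)
        _mm(H, GtG, SS1)
        _mmT(SS1, H, SS2)  # H G^T G H^T
        _mm(F, SS2, denF)
        for i in range(L):
            for j in range(S):
                v = (
                    F[i, j]
                    * (XGHt[i, j] + a * c0[i] * F0[i, j])
                    / (denF[i, j] + a * c0[i] * F[i, j] + eps)
                )
                # floor vanishing entries well above the subnormal range;
                # 1e-100 is exact zero at the working scale but avoids the
                # large slowdown of denormal arithmetic in the late iterations
                F[i, j] = v if v > 1e-100 else 1e-100
        # H update (new F, old G)
        _mTm(F, F, FtF)
        _mTm(F, X, FtX)
        _mm(FtX, G, SS1)  # F^T X G
        _mm(FtF, H, SS2)
        _mm(SS2, GtG, SS3)  # F^T F H G^T G
        for i in range(S):
            for j in range(S):
                v = H[i, j] * SS1[i, j] / (SS3[i, j] + eps)
                H[i, j] = v if v > 1e-100 else 1e-100
        # G update (new F, new H)
        _mTm(FtX, H, XtFH)  # (F^T X)^T H = X^T F H
        _mm(FtF, H, SS1)
        _mTm(H, SS1, SS2)  # H^T F^T F H
        _mm(G, SS2, denG)
        for i in range(K):
            for j in range(S):
                v = (
                    G[i, j]
                    * (XtFH[i, j] + b * c1[i] * G0[i, j])
                    / (denG[i, j] + b * c1[i] * G[i, j] + eps)
                )
                G[i, j] = v if v > 1e-100 else 1e-100
        _mTm(G, G, GtG)
        # objective via the algebraic expansion
        cross = 0.0
        for i in range(K):
            for j in range(S):
                cross += XtFH[i, j] * G[i, j]
        quad = 0.0
        for i in range(S):
            for j in range(S):
                quad += SS2[i, j] * GtG[i, j]
        pen = 0.0
        for i in range(L):
            if c0[i] > 0.0:
                for j in range(S):
                    d = F[i, j] - F0[i, j]
                    pen += a * d * d
        for i in range(K):
            if c1[i] > 0.0:
                for j in range(S):
                    d = G[i, j] - G0[i, j]
                    pen += b * d * d
        obj = X2 - 2.0 * cross + quad + pen
        trace[it] = obj
        n_done = it + 1
        if not np.isfinite(obj):
            break
        if tol > 0.0 and abs(prev - obj) <= tol * abs(prev):
            converged = True
            break
        prev = obj
    return F, H, G, trace, n_done, converged


def fit_semi_nmf(
    X: np.ndarray,
    constraints: LabelConstraints,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    eps: float = EPSILON,
    update_rule: str = "monotone",
) -> FactorizationResult:
    """Iterate the multiplicative updates until the objective stalls.

    Stops when the relative objective change drops below ``tol`` (or after
    ``max_iter`` iterations) and then normalizes each row of F and G to sum
    to 1.  The main loop shares the two large matrix products (X G and F^T X)
    between the updates and an algebraic expansion of the objective,

        ||X - F H G^T||^2 = ||X||^2 - 2 <X^T F H, G> + <H^T F^T F H, G^T G>,

    so each iteration costs two L x K multiplications.  ``update_step``
    applied to the same factors produces identical iterates (tested); the
    projection rule falls back to plain per-iteration evaluation.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if X.shape[0] != constraints.F0.shape[0] or X.shape[1] != constraints.G0.shape[0]:
        raise ValueError("constraints do not match the shape of X")
    F, H, G = _init_factors(X, constraints, seed)

    a, b = constraints.alpha, constraints.beta
    F0, G0 = constraints.F0, constraints.G0
    c0 = constraints.c0[:, None]
    c1 = constraints.c1[:, None]
    labeled0 = constraints.c0 > 0
    labeled1 = constraints.c1 > 0
    X2 = float((X * X).sum())

    def penalties(F: np.ndarray, G: np.ndarray) -> float:
        return float(
            a * ((F[labeled0] - F0[labeled0]) ** 2).sum()
            + b * ((G[labeled1] - G0[labeled1]) ** 2).sum()
        )

    prev_obj = objective_value(X, F, H, G, constraints)
    initial_objective = prev_obj

    if update_rule == "monotone" and _HAVE_NUMBA:
        F, H, G, raw_trace, iterations, converged = _monotone_loop(
            np.ascontiguousarray(X),
            np.ascontiguousarray(F),
            np.ascontiguousarray(H),
            np.ascontiguousarray(G),
            np.ascontiguousarray(F0),
            np.ascontiguousarray(G0),
            constraints.c0,
            constraints.c1,
            float(a),
            float(b),
            float(eps),
            int(max_iter),
            float(tol),
            float(prev_obj),
        )
        trace_arr = raw_trace[:iterations]
        if not np.all(np.isfinite(trace_arr)) or not (
            np.all(np.isfinite(F)) and np.all(np.isfinite(H)) and np.all(np.isfinite(G))
        ):
            for name, M in (("F", F), ("H", H), ("G", G)):
                if not np.all(np.isfinite(M)):
                    raise NumericalError(
                        f"{name} became non-finite at iteration {iterations}"
                    )
            raise NumericalError(f"objective became non-finite at iteration {iterations}")
        residual = kkt_residual(X, F, H, G, constraints)
        return FactorizationResult(
            F=_normalize_rows(F),
            H=H,
            G=_normalize_rows(G),
            F_raw=F,
            G_raw=G,
            objective_trace=trace_arr.copy(),
            initial_objective=initial_objective,
            iterations=iterations,
            converged=converged,
            kkt_residual_F=residual,
            seed=seed,
        )

    trace: list[float] = []
    converged = False
    GtG = G.T @ G
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        if update_rule == "monotone":
            XG = X @ G
            F = F * (XG @ H.T + a * c0 * F0) / (F @ (H @ GtG @ H.T) + a * c0 * F + eps)
            _check_finite("F", F, it)
            FtF = F.T @ F
            FtX = F.T @ X
            H = H * (FtX @ G) / (FtF @ H @ GtG + eps)
            _check_finite("H", H, it)
            XtFH = FtX.T @ H
            HtFtFH = H.T @ FtF @ H
            G = G * (XtFH + b * c1 * G0) / (G @ HtFtFH + b * c1 * G + eps)
            _check_finite("G", G, it)
            GtG = G.T @ G
            obj = (
                X2
                - 2.0 * float((XtFH * G).sum())
                + float((HtFtFH * GtG).sum())
                + penalties(F, G)
            )
        else:
            F, H, G = update_step(
                X, F, H, G, constraints, eps=eps, update_rule=update_rule, iteration=it
            )
            obj = objective_value(X, F, H, G, constraints)
        trace.append(obj)
        if tol > 0 and abs(prev_obj - obj) <= tol * abs(prev_obj):
            converged = True
            prev_obj = obj
            break
        prev_obj = obj

    residual = kkt_residual(X, F, H, G, constraints)
    return FactorizationResult(
        F=_normalize_rows(F),
        H=H,
        G=_normalize_rows(G),
        F_raw=F,
        G_raw=G,
        objective_trace=np.asarray(trace),
        initial_objective=initial_objective,
        iterations=iterations,
        converged=converged,
        kkt_residual_F=residual,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence

def save_result(result: FactorizationResult, directory: str | Path) -> None:
    """Persist factors as delimited matrices plus a JSON metadata header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("F", "H", "G", "F_raw", "G_raw"):
        np.savetxt(directory / f"{name}.csv", getattr(result, name), delimiter=",")
    meta = {
        "shape_F": list(result.F.shape),
        "shape_G": list(result.G.shape),
        "iterations": result.iterations,
        "converged": result.converged,
        "initial_objective": result.initial_objective,
        "objective": result.objective,
        "kkt_residual_F": result.kkt_residual_F,
        "seed": result.seed,
    }
    (directory / "factorization.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(
        directory / "objective_trace.csv", result.objective_trace, delimiter=","
    )


def load_result(directory: str | Path) -> FactorizationResult:
    directory = Path(directory)
    meta = json.loads((directory / "factorization.json").read_text())
    mats = {
        name: np.atleast_2d(np.loadtxt(directory / f"{name}.csv", delimiter=","))
        for name in ("F", "H", "G", "F_raw", "G_raw")
    }
    trace = np.atleast_1d(np.loadtxt(directory / "objective_trace.csv", delimiter=","))
    return FactorizationResult(
        F=mats["F"],
        H=mats["H"],
        G=mats["G"],
        F_raw=mats["F_raw"],
        G_raw=mats["G_raw"],
        objective_trace=trace,
        initial_objective=meta["initial_objective"],
        iterations=meta["iterations"],
        converged=meta["converged"],
        kkt_residual_F=meta["kkt_residual_F"],
        seed=meta["seed"],
    )
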