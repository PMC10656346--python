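"""Generalized EM with a coordinate-descent M-step for penalized factor analysis.

The latent factors are treated as missing data.  Each EM iteration computes
the conditional sufficient statistics

    M = Phi Lambda^T Sigma^{-1},  B = S M^T,  A = M S M^T + Phi - M Lambda Phi,

after which the expected complete-data loss separates over the rows of
Lambda: row i contributes (s_ii - 2 l_i^T b_i + l_i^T A l_i) / (2 psi_i)
plus its penalty.  One cyclic coordinate-descent sweep per M-step suffices
for a generalized EM — every coordinate update solves its one-dimensional
problem exactly, so the penalized discrepancy never increases.

For rho -> infinity under the prenet penalty the row minimizer has a closed
form: put the single nonzero at the column maximizing b_ik^2 / a_kk.  That
yields an exact perfect-simple-structure (PSS) solver, ``fit_pss``, run from
many random starts because the large-rho problem is multimodal (as k-means
is).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf

import numpy as np
from scipy import linalg

from .model import (
    FactorModel,
    SampleCov,
    discrepancy,
    implied_covariance,
    penalized_objective,
)
from .penalties import PenaltySpec

__all__ = [
    "EMStats",
    "FitResult",
    "PSI_FLOOR",
    "estep_stats",
    "row_coordinate_update",
    "large_rho_row_update",
    "update_uniquenesses",
    "update_factor_corr",
    "cold_start",
    "fit_em",
    "fit_pss",
]

logger = logging.getLogger(__name__)

#: lower bound on unique variances (guards against Heywood collapse)
PSI_FLOOR = 1e-3


@dataclass
class EMStats:
    """E-step sufficient statistics: A (m x m) and B (p x m, rows b_i)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        m = self.A.shape[0]
        if self.A.shape != (m, m) or self.B.shape[1] != m:
            raise ValueError("incompatible shapes for A and B")


@dataclass
class FitResult:
    """Outcome of one penalized EM fit."""

    model: FactorModel
    objective: float
    n_iterations: int
    converged: bool
    objective_trace: np.ndarray
    spec: PenaltySpec | None = None
    n_psi_floor_hits: int = 0
    discrepancy: float = float("nan")

    @property
    def loadings(self) -> np.ndarray:
        return self.model.loadings


def estep_stats(S: SampleCov, model: FactorModel) -> EMStats:
    """Conditional sufficient statistics of the factors given the data.

    With ``M = Phi Lambda^T Sigma^{-1}``:  ``B = S M^T`` and
    ``A = M S M^T + Phi - M Lambda Phi`` (posterior second moment of the
    factors averaged over the sample).
    """
    Sigma = implied_covariance(model)
    try:
        c, low = linalg.cho_factor(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "model-implied covariance Sigma is singular in the E-step"
        ) from exc
    Phi = model.factor_corr
    L = model.loadings
    # M^T = Sigma^{-1} Lambda Phi  (p x m)
    Mt = linalg.cho_solve((c, low), L @ Phi)
    B = S.S @ Mt
    A = Mt.T @ B + Phi - Mt.T @ L @ Phi
    A = 0.5 * (A + A.T)
    return EMStats(A=A, B=B)


def _soft(z: np.ndarray | float, t: np.ndarray | float):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _mcp_coordinate_exact(ajj: float, z: float, psi: float, rho: float,
                          gamma: float) -> float:
    """Exact minimizer of (ajj l^2 - 2 z l)/(2 psi) + MCP(l; rho, gamma).

    Used when the coordinate problem is nonconvex (ajj <= psi / gamma); the
    objective is piecewise quadratic, so the minimum is at a stationary point
    of one of the pieces or at a kink (0, +-rho*gamma).
    """
    def g(lam: float) -> float:
        a = abs(lam)
        pen = rho * a - a * a / (2.0 * gamma) if a <= rho * gamma \
            else 0.5 * rho * rho * gamma
        return (ajj * lam * lam - 2.0 * z * lam) / (2.0 * psi) + pen

    cands = [0.0]
    bound = rho * gamma
    denom = ajj / psi - 1.0 / gamma
    for s in (1.0, -1.0):
        if denom != 0.0:
            lam = (z / psi - s * rho) / denom
            if 0.0 < s * lam < bound:
                cands.append(lam)
        cands.append(s * bound)
    if ajj > 0:
        lam2 = z / ajj
        if abs(lam2) >= bound:
            cands.append(lam2)
    return min(cands, key=g)


def _cd_sweep(Lam: np.ndarray, stats: EMStats, psi: np.ndarray,
              spec: PenaltySpec) -> np.ndarray:
    """One cyclic coordinate-descent sweep over columns, all rows at once.

    Rows of Lambda are independent M-step problems, so updating column j
    simultaneously for every row is identical to per-row cyclic sweeps.
    """
    A, B = stats.A, stats.B
    m = A.shape[0]
    rho, gamma = spec.rho, spec.gamma
    Lam = Lam.copy()
    for j in range(m):
        others = [k for k in range(m) if k != j]
        z = B[:, j] - Lam[:, others] @ A[j, others]
        ajj = A[j, j]
        if spec.family == "prenet":
            s_abs = np.abs(Lam[:, others]).sum(axis=1)
            s_sq = (Lam[:, others] ** 2).sum(axis=1)
            thresh = rho * psi * gamma * s_abs
            denom = ajj + rho * psi * (1.0 - gamma) * s_sq
            Lam[:, j] = _soft(z, thresh) / denom
        elif spec.family == "lasso":
            Lam[:, j] = _soft(z, rho * psi) / ajj
        elif spec.family == "enet":
            Lam[:, j] = _soft(z, rho * psi * gamma) / (
                ajj + rho * psi * (1.0 - gamma)
            )
        else:  # mcp (firm thresholding; exact piecewise search if nonconvex)
            new = np.empty_like(z)
            convex = ajj > psi / gamma
            if np.any(convex):
                lam1 = _soft(z[convex], rho * psi[convex]) / (
                    ajj - psi[convex] / gamma
                )
                lam2 = z[convex] / ajj
                new[convex] = np.where(np.abs(lam1) <= rho * gamma, lam1, lam2)
            idx = np.flatnonzero(~convex)
            if idx.size:
                logger.debug(
                    "mcp coordinate %d nonconvex for %d rows; exact search",
                    j, idx.size,
                )
                for i in idx:
                    new[i] = _mcp_coordinate_exact(
                        ajj, z[i], psi[i], rho, gamma
                    )
            Lam[:, j] = new
    return Lam


def row_coordinate_update(
    lam_row: np.ndarray,
    stats: EMStats,
    row_index: int,
    psi_i: float,
    spec: PenaltySpec,
) -> np.ndarray:
    """One full cyclic coordinate sweep for a single row of Lambda.

    For the prenet penalty each coordinate is set to

        Soft(b_ij - sum_{k!=j} a_jk l_ik, rho psi_i gamma sum_{k!=j}|l_ik|)
        / (a_jj + rho psi_i (1-gamma) sum_{k!=j} l_ik^2),

    the exact minimizer of the penalized quadratic row approximation in that
    coordinate; note that when the partner loadings are all zero the update
    is the *unshrunk* least-squares value b_ij / a_jj — the mechanism that
    lets the prenet keep one large loading per row at any rho.
    """
    if psi_i <= 0:
        raise ValueError("psi_i must be strictly positive")
    if spec.is_pss:
        raise ValueError("use large_rho_row_update for rho = inf")
    row = np.asarray(lam_row, dtype=float).reshape(1, -1)
    sub = EMStats(stats.A, stats.B[row_index : row_index + 1])
    return _cd_sweep(row, sub, np.array([psi_i]), spec)[0]


def large_rho_row_update(stats: EMStats, row_index: int) -> np.ndarray:
    """Closed-form row minimizer under the prenet penalty as rho -> inf.

    Selects j = argmax_k b_ik^2 / a_kk (smallest index on ties), sets
    l_ij = b_ij / a_jj and every other entry to exact zero.
    """
    a_diag = np.diag(stats.A)
    if np.any(a_diag <= 0):
        raise ValueError("diagonal of A must be strictly positive")
    b = stats.B[row_index]
    row = np.zeros_like(b)
    if np.all(b == 0.0):
        return row
    j = int(np.argmax(b**2 / a_diag))
    row[j] = b[j] / a_diag[j]
    return row


def _pss_mstep_loadings(stats: EMStats) -> np.ndarray:
    a_diag = np.diag(stats.A)
    scores = stats.B**2 / a_diag
    j = np.argmax(scores, axis=1)  # smallest index wins ties
    Lam = np.zeros_like(stats.B)
    rows = np.arange(stats.B.shape[0])
    Lam[rows, j] = stats.B[rows, j] / a_diag[j]
    Lam[np.all(stats.B == 0.0, axis=1)] = 0.0
    return Lam


def update_uniquenesses(
    S: SampleCov, loadings: np.ndarray, stats: EMStats,
    floor: float = PSI_FLOOR,
) -> tuple[np.ndarray, int]:
    """M-step unique variances psi_i = s_ii - 2 l_i^T b_i + l_i^T A l_i.

    Values below ``floor`` are clipped (Heywood guard); the number of floor
    hits is returned alongside and logged.
    """
    L = loadings
    raw = (
        np.diag(S.S)
        - 2.0 * (L * stats.B).sum(axis=1)
        + ((L @ stats.A) * L).sum(axis=1)
    )
    hits = int((raw < floor).sum())
    if hits:
        logger.warning("unique-variance floor hit for %d variable(s)", hits)
    return np.maximum(raw, floor), hits


def update_factor_corr(stats: EMStats) -> np.ndarray:
    """Rescale A to a correlation matrix: Phi = D^{-1/2} A D^{-1/2}."""
    A = stats.A
    if np.linalg.eigvalsh(A)[0] <= 0:
        raise np.linalg.LinAlgError("E-step matrix A is not positive definite")
    d = 1.0 / np.sqrt(np.diag(A))
    Phi = A * np.outer(d, d)
    np.fill_diagonal(Phi, 1.0)
    return 0.5 * (Phi + Phi.T)


def _phi_surrogate(Phi: np.ndarray, A: np.ndarray, zeta: float) -> float:
    c = linalg.cholesky(Phi, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    tr = float(np.trace(linalg.cho_solve((c, True), A)))
    return 0.5 * (logdet + tr) - zeta * logdet


def cold_start(
    S: SampleCov, m: int, rng: np.random.Generator,
    orientation: str = "orthogonal",
) -> FactorModel:
    """Random initial model: Lambda_ij ~ U(-1,1) * sqrt(s_ii / m), Psi = diag(S)/2."""
    d = np.diag(S.S)
    Lam = rng.uniform(-1.0, 1.0, size=(S.p, m)) * np.sqrt(d / m)[:, None]
    psi = np.maximum(d / 2.0, PSI_FLOOR)
    return FactorModel(Lam, np.eye(m), psi, orientation)


def fit_em(
    S: SampleCov,
    init: FactorModel,
    spec: PenaltySpec,
    tol: float = 1e-7,
    max_iter: int = 1000,
    n_sweeps: int = 1,
) -> FitResult:
    """Generalized EM for the penalized discrepancy at a finite rho.

    Alternates the E-step statistics, ``n_sweeps`` coordinate-descent sweeps
    over the rows of Lambda, the unique-variance update and (oblique models)
    the factor-correlation update, until the relative objective change drops
    below ``tol`` or ``max_iter`` is reached.  Non-convergence returns the
    last iterate with ``converged=False``.  The objective trace is
    non-increasing up to floating-point slack.
    """
    if spec.is_pss:
        raise ValueError("fit_em requires a finite rho; use fit_pss")
    model = init.copy()
    model.uniquenesses = np.maximum(model.uniquenesses, PSI_FLOOR)
    obj = penalized_objective(S, model, spec)
    trace = [obj]
    converged = False
    floor_hits = 0
    for it in range(1, max_iter + 1):
        stats = estep_stats(S, model)
        Lam = model.loadings
        for _ in range(n_sweeps):
            Lam = _cd_sweep(Lam, stats, model.uniquenesses, spec)
        psi, hits = update_uniquenesses(S, Lam, stats)
        floor_hits += hits
        model.loadings = Lam
        model.uniquenesses = psi
        if model.orientation == "oblique":
            try:
                cand = update_factor_corr(stats)
                if _phi_surrogate(cand, stats.A, spec.zeta) <= _phi_surrogate(
                    model.factor_corr, stats.A, spec.zeta
                ):
                    model.factor_corr = cand
            except np.linalg.LinAlgError:
                logger.warning("skipping Phi update: A not positive definite")
        new_obj = penalized_objective(S, model, spec)
        trace.append(new_obj)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    return FitResult(
        model=model,
        objective=obj,
        n_iterations=it,
        converged=converged,
        objective_trace=np.asarray(trace),
        spec=spec,
        n_psi_floor_hits=floor_hits,
        discrepancy=discrepancy(S, model),
    )


def _fit_pss_single(
    S: SampleCov, init: FactorModel, tol: float, max_iter: int
) -> FitResult:
    model = init.copy()
    model.uniquenesses = np.maximum(model.uniquenesses, PSI_FLOOR)
    obj = discrepancy(S, model)
    trace = [obj]
    converged = False
    floor_hits = 0
    for it in range(1, max_iter + 1):
        stats = estep_stats(S, model)
        Lam = _pss_mstep_loadings(stats)
        psi, hits = update_uniquenesses(S, Lam, stats)
        floor_hits += hits
        model.loadings = Lam
        model.uniquenesses = psi
        if model.orientation == "oblique":
            try:
                cand = update_factor_corr(stats)
                if _phi_surrogate(cand, stats.A, 0.0) <= _phi_surrogate(
                    model.factor_corr, stats.A, 0.0
                ):
                    model.factor_corr = cand
            except np.linalg.LinAlgError:
                pass
        new_obj = discrepancy(S, model)
        trace.append(new_obj)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    return FitResult(
        model=model,
        objective=obj,
        n_iterations=it,
        converged=converged,
        objective_trace=np.asarray(trace),
        spec=PenaltySpec("prenet", 1.0, inf),
        n_psi_floor_hits=floor_hits,
        discrepancy=obj,
    )


def fit_pss(
    S: SampleCov,
    m: int,
    n_starts: int = 10,
    seed: int | np.random.Generator | None = 0,
    orientation: str = "orthogonal",
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> FitResult:
    """Perfect-simple-structure fit (prenet, rho -> infinity).

    Runs the closed-form large-rho EM from ``n_starts`` random initial
    models and returns the lowest-discrepancy fit.  Every M-step produces a
    loading matrix with at most one (exact) nonzero per row, so the penalty
    term is identically zero and the objective is the plain discrepancy.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    for _ in range(max(1, n_starts)):
        init = cold_start(S, m, rng, orientation)
        fit = _fit_pss_single(S, init, tol, max_iter)
        if best is None or fit.objective < best.objective:
            best = fit
    assert best is not None
    return best
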