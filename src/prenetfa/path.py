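"""Solution paths over the regularization parameter and model selection.

The path starts at ``rho_max`` — the smallest rho at which the prenet fit
collapses to a perfect simple structure, available in closed form from the
coordinate-descent threshold condition — and marches down a log-equispaced
grid to ``rho_max * delta * sqrt(gamma)``, warm-starting each fit from its
predecessor (or refitting from random starts in cold mode).  rho is then
chosen by AIC, BIC or cross-validated held-out discrepancy.  Because
columns of the loading matrix can be shrunk to exact zero vectors, the path
also performs an implicit selection of the number of factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import FitResult, cold_start, estep_stats, fit_em, fit_pss
from .model import ZERO_TOL, SampleCov, discrepancy, is_perfect_simple
from .penalties import PenaltySpec

__all__ = [
    "PathResult",
    "rho_max",
    "rho_grid",
    "solution_path",
    "count_nonzero_params",
    "information_criteria",
    "effective_factors",
    "select_model",
    "cross_validate",
]


@dataclass
class PathResult:
    """Ordered fits along a decreasing rho grid with selection criteria."""

    gamma: float
    rho_grid: np.ndarray
    fits: list[FitResult]
    aic: np.ndarray
    bic: np.ndarray
    p0: np.ndarray
    start_mode: str
    family: str = "prenet"

    def __len__(self) -> int:
        return len(self.fits)

    def to_frame(self) -> pd.DataFrame:
        """One row per rho: objective, p0, AIC, BIC, effective factors, convergence."""
        return pd.DataFrame(
            {
                "rho": self.rho_grid,
                "objective": [f.objective for f in self.fits],
                "discrepancy": [f.discrepancy for f in self.fits],
                "p0": self.p0,
                "aic": self.aic,
                "bic": self.bic,
                "effective_factors": [
                    effective_factors(f.model.loadings) for f in self.fits
                ],
                "converged": [f.converged for f in self.fits],
            }
        )


def rho_max(S: SampleCov, pss_fit: FitResult, gamma: float) -> float:
    """Smallest rho producing the perfect simple structure.

    At a PSS fit with row i loaded on column j, the coordinate-descent
    soft threshold keeps every cross loading k != j at zero iff

        rho >= |b_ik - a_kj l_ij| / (gamma psi_i |l_ij|),

    so rho_max is the maximum of the right-hand side over rows with a
    nonzero loading and their cross columns.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    Lam = pss_fit.model.loadings
    flag, cols = is_perfect_simple(Lam)
    if not flag:
        raise ValueError("rho_max requires a perfect-simple-structure fit")
    if all(c is None for c in cols):
        raise ValueError("rho_max undefined for an all-zero loading matrix")
    stats = estep_stats(S, pss_fit.model)
    psi = pss_fit.model.uniquenesses
    m = Lam.shape[1]
    best = 0.0
    for i, j in enumerate(cols):
        if j is None:
            continue
        lam_ij = Lam[i, j]
        for k in range(m):
            if k == j:
                continue
            val = abs(stats.B[i, k] - stats.A[k, j] * lam_ij) / (
                gamma * psi[i] * abs(lam_ij)
            )
            best = max(best, val)
    return best


def rho_grid(
    rho_max_value: float, gamma: float, K: int = 30, delta: float = 0.001
) -> np.ndarray:
    """K log-equispaced values from rho_max down to rho_max * delta * sqrt(gamma)."""
    if rho_max_value <= 0:
        raise ValueError("rho_max must be positive")
    if K < 2:
        raise ValueError("K must be >= 2")
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    lo = rho_max_value * delta * np.sqrt(gamma)
    return np.geomspace(rho_max_value, lo, K)


def count_nonzero_params(fit: FitResult) -> int:
    """p0 = #nonzero loadings + p unique variances + m(m-1)/2 if oblique."""
    model = fit.model
    p0 = int((np.abs(model.loadings) > ZERO_TOL).sum()) + model.p
    if model.orientation == "oblique":
        p0 += model.m * (model.m - 1) // 2
    return p0


def information_criteria(fit: FitResult, n: int) -> tuple[float, float]:
    """(AIC, BIC) = 2n l_DF + {2, log n} * p0.

    Up to an additive constant (the saturated-model log-likelihood) this is
    the usual -2 loglik + penalty, so rankings across fits are unchanged.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    p0 = count_nonzero_params(fit)
    base = 2.0 * n * fit.discrepancy
    return base + 2.0 * p0, base + p0 * np.log(n)


def effective_factors(loadings: np.ndarray, tol: float = ZERO_TOL) -> int:
    """Number of columns of Lambda with at least one nonzero entry."""
    return int((np.abs(loadings) > tol).any(axis=0).sum())


def solution_path(
    S: SampleCov,
    m: int,
    spec: PenaltySpec,
    K: int = 30,
    delta: float = 0.001,
    start_mode: str = "warm",
    n_starts: int = 10,
    seed: int | np.random.Generator | None = 0,
    orientation: str = "orthogonal",
    grid: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> PathResult:
    """Fit the whole regularization path for one penalty family and gamma.

    Warm mode fits the perfect simple structure at the top of the grid
    (multi-start) and then marches down, initializing each fit at the
    previous solution; cold mode refits each grid point from ``n_starts``
    random initial models and keeps the best.  The top of the grid is the
    prenet ``rho_max``; for element-wise families (which have no finite
    PSS point) the same grid anchors the path at a comparably strong
    shrinkage level.
    """
    if start_mode not in ("warm", "cold"):
        raise ValueError(f"unknown start_mode {start_mode!r}")
    rng = np.random.default_rng(seed)
    pss = fit_pss(
        S, m, n_starts=n_starts, seed=rng, orientation=orientation,
        tol=tol, max_iter=max_iter,
    )
    if grid is None:
        g = spec.gamma if spec.family in ("prenet", "enet") else 1.0
        top = rho_max(S, pss, g)
        if top <= 0.0:
            # degenerate PSS fit (e.g. collapsed columns): every cross
            # statistic vanishes, so any rho keeps the pattern; anchor the
            # grid at the threshold scale that would shrink even the main
            # loadings, the only remaining scale in the problem
            stats = estep_stats(S, pss.model)
            top = float(
                np.max(np.abs(stats.B) / (g * pss.model.uniquenesses[:, None]))
            )
        if top <= 0.0:
            raise ValueError("cannot anchor the rho grid: all statistics vanish")
        grid = rho_grid(top, spec.gamma, K, delta)
    grid = np.asarray(grid, dtype=float)
    fits: list[FitResult] = []
    current = pss.model
    for k, rho_k in enumerate(grid):
        spec_k = spec.with_rho(float(rho_k))
        if start_mode == "warm":
            if k == 0 and spec.family == "prenet":
                # at rho >= rho_max the prenet solution IS the PSS fit
                # (penalty exactly zero), so reuse it as the top-of-grid fit
                fit = FitResult(
                    model=pss.model.copy(),
                    objective=pss.objective,
                    n_iterations=pss.n_iterations,
                    converged=pss.converged,
                    objective_trace=pss.objective_trace,
                    spec=spec_k,
                    n_psi_floor_hits=pss.n_psi_floor_hits,
                    discrepancy=pss.discrepancy,
                )
            else:
                fit = fit_em(S, current, spec_k, tol=tol, max_iter=max_iter)
            current = fit.model
        else:
            fit = fit_em(S, pss.model, spec_k, tol=tol, max_iter=max_iter)
            for _ in range(max(0, n_starts - 1)):
                cand = fit_em(
                    S, cold_start(S, m, rng, orientation), spec_k,
                    tol=tol, max_iter=max_iter,
                )
                if cand.objective < fit.objective:
                    fit = cand
        fits.append(fit)
    aic_bic = [information_criteria(f, S.n) for f in fits]
    return PathResult(
        gamma=spec.gamma,
        rho_grid=grid,
        fits=fits,
        aic=np.array([ab[0] for ab in aic_bic]),
        bic=np.array([ab[1] for ab in aic_bic]),
        p0=np.array([count_nonzero_params(f) for f in fits]),
        start_mode=start_mode,
        family=spec.family,
    )


def select_model(path: PathResult, criterion: str = "bic") -> tuple[FitResult, int]:
    """Criterion-minimizing fit and its effective number of factors.

    Ties are broken toward the largest rho (sparsest fit); criterion is
    "aic" or "bic".
    """
    if len(path) == 0:
        raise ValueError("empty path")
    values = {"aic": path.aic, "bic": path.bic}[criterion]
    idx = int(np.argmin(values))  # grid is decreasing, argmin takes largest rho
    fit = path.fits[idx]
    return fit, effective_factors(fit.model.loadings)


def _heldout_gaussian_loss(S_test: np.ndarray, model) -> float:
    from scipy import linalg

    Sigma = model.implied_covariance()
    c, low = linalg.cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    tr = float(np.trace(linalg.cho_solve((c, low), S_test)))
    return 0.5 * (logdet + tr)


def cross_validate(
    X: np.ndarray,
    m: int,
    spec: PenaltySpec,
    folds: int = 10,
    K: int = 30,
    delta: float = 0.001,
    seed: int = 0,
    orientation: str = "orthogonal",
    n_starts: int = 10,
    start_mode: str = "warm",
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Select rho by K-fold cross-validated held-out discrepancy.

    A common grid (anchored at the full-data rho_max) is used in every
    fold; each fold fits the path on the training covariance and scores
    every rho by the Gaussian loss of the held-out sample covariance at the
    trained parameters, (log|Sigma| + tr(Sigma^{-1} S_test))/2 — the
    held-out discrepancy up to a rho-independent constant, and well defined
    even when the held-out covariance is singular (n_test <= p).
    Returns ``(rho_selected, grid, mean_scores)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < 2 * folds:
        raise ValueError("each fold needs at least 2 held-out rows")
    rng = np.random.default_rng(seed)
    full = SampleCov.from_data(X)
    pss = fit_pss(full, m, n_starts=n_starts, seed=rng, orientation=orientation)
    g = spec.gamma if spec.family in ("prenet", "enet") else 1.0
    grid = rho_grid(rho_max(full, pss, g), spec.gamma, K, delta)
    perm = rng.permutation(n)
    scores = np.zeros((folds, len(grid)))
    for f, test_idx in enumerate(np.array_split(perm, folds)):
        train_idx = np.setdiff1d(perm, test_idx)
        S_train = SampleCov.from_data(X[train_idx])
        S_test = SampleCov.from_data(X[test_idx])
        path = solution_path(
            S_train, m, spec, grid=grid, start_mode=start_mode,
            n_starts=n_starts, seed=rng, orientation=orientation,
            tol=tol, max_iter=max_iter,
        )
        for k, fit in enumerate(path.fits):
            scores[f, k] = _heldout_gaussian_loss(S_test.S, fit.model)
    mean_scores = scores.mean(axis=0)
    return float(grid[int(np.argmin(mean_scores))]), grid, mean_scores
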