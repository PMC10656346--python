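"""Factor model containers, implied covariance and the ML discrepancy.

The oblique common-factor model for a p-vector X with mean 0 is

    X = Lambda F + eps,   Cov(F) = Phi,   Cov(eps) = Psi (diagonal),

so Sigma = Lambda Phi Lambda^T + Psi.  Fitting minimizes the maximum
likelihood discrepancy

    l_DF(theta) = (tr(Sigma^{-1} S) - log|Sigma^{-1} S| - p) / 2,

which is nonnegative and zero iff Sigma = S, optionally plus a penalty on
the loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .penalties import PenaltySpec, penalty_value

__all__ = [
    "FactorModel",
    "SampleCov",
    "implied_covariance",
    "discrepancy",
    "penalized_objective",
    "is_perfect_simple",
    "ZERO_TOL",
]

#: entries with |lambda| <= ZERO_TOL are treated as structural zeros
ZERO_TOL = 1e-10


@dataclass
class FactorModel:
    """Parameters (Lambda, Phi, Psi) of a p-variable, m-factor model.

    Attributes
    ----------
    loadings : (p, m) ndarray
        Factor loading matrix Lambda.
    factor_corr : (m, m) ndarray
        Factor correlation matrix Phi (identity for orthogonal models).
    uniquenesses : (p,) ndarray
        Unique (specific) variances, the diagonal of Psi; all > 0.
    orientation : {"orthogonal", "oblique"}
    """

    loadings: np.ndarray
    factor_corr: np.ndarray = None  # type: ignore[assignment]
    uniquenesses: np.ndarray = None  # type: ignore[assignment]
    orientation: str = "orthogonal"

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        p, m = self.loadings.shape
        if m < 1 or p < m:
            raise ValueError(f"need p >= m >= 1, got p={p}, m={m}")
        if self.orientation not in ("orthogonal", "oblique"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.factor_corr is None or self.orientation == "orthogonal":
            self.factor_corr = np.eye(m)
        else:
            self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        if self.uniquenesses is None:
            self.uniquenesses = np.ones(p)
        else:
            self.uniquenesses = np.asarray(self.uniquenesses, dtype=float).ravel()
        self._validate()

    def _validate(self) -> None:
        p, m = self.loadings.shape
        Phi = self.factor_corr
        if Phi.shape != (m, m):
            raise ValueError(f"factor_corr must be {m}x{m}, got {Phi.shape}")
        if not np.allclose(Phi, Phi.T, atol=1e-8):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(Phi), 1.0, atol=1e-8):
            raise ValueError("factor_corr must have a unit diagonal")
        if np.linalg.eigvalsh(Phi)[0] <= 0:
            raise ValueError("factor_corr must be positive definite")
        if self.uniquenesses.shape != (p,):
            raise ValueError(
                f"uniquenesses must have length {p}, got {self.uniquenesses.shape}"
            )
        if np.any(self.uniquenesses <= 0):
            raise ValueError("all unique variances must be strictly positive")

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def implied_covariance(self) -> np.ndarray:
        return implied_covariance(self)

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.loadings.copy(),
            self.factor_corr.copy(),
            self.uniquenesses.copy(),
            self.orientation,
        )


@dataclass
class SampleCov:
    """A p x p sample covariance (or correlation) matrix with its sample size."""

    S: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        p, q = self.S.shape
        if p != q:
            raise ValueError(f"S must be square, got {self.S.shape}")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        if np.any(np.diag(self.S) <= 0):
            raise ValueError("S must have a strictly positive diagonal")
        self.S = 0.5 * (self.S + self.S.T)
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_data(cls, X, standardize: bool = False) -> "SampleCov":
        """Sample covariance of an n x p data table (denominator n - 1)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        if standardize:
            Xc = Xc / Xc.std(axis=0, ddof=1)
        return cls(Xc.T @ Xc / (n - 1), n)


def implied_covariance(model: FactorModel) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda Phi Lambda^T + Psi."""
    L, Phi = model.loadings, model.factor_corr
    Sigma = L @ Phi @ L.T + np.diag(model.uniquenesses)
    return 0.5 * (Sigma + Sigma.T)


def _logdet_pd(A: np.ndarray, name: str) -> float:
    try:
        c = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{name} is not positive definite") from exc
    return float(2.0 * np.log(np.diag(c)).sum())


def discrepancy(S: SampleCov, model: FactorModel) -> float:
    """Maximum likelihood discrepancy (tr(Sigma^-1 S) - log|Sigma^-1 S| - p)/2.

    Nonnegative for positive definite S and Sigma; zero iff Sigma = S.
    Raises ``numpy.linalg.LinAlgError`` naming the offending matrix when S or
    Sigma is not positive definite.
    """
    Sigma = implied_covariance(model)
    p = S.p
    if Sigma.shape[0] != p:
        raise ValueError(f"model is {Sigma.shape[0]}-variate but S is {p}-variate")
    logdet_S = _logdet_pd(S.S, "sample covariance S")
    try:
        c, low = linalg.cho_factor(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "model-implied covariance Sigma is not positive definite"
        ) from exc
    logdet_Sigma = 2.0 * np.log(np.diag(c)).sum()
    tr = float(np.trace(linalg.cho_solve((c, low), S.S)))
    return 0.5 * (tr - (logdet_S - logdet_Sigma) - p)


def penalized_objective(
    S: SampleCov, model: FactorModel, spec: PenaltySpec
) -> float:
    """Penalized loss l_DF + rho P(Lambda) [- zeta log|Phi| when zeta > 0].

    The stabilizer term ``-zeta log|Phi|`` grows as Phi approaches
    singularity, discouraging degenerate factor correlations.
    """
    value = discrepancy(S, model) + penalty_value(model.loadings, spec)
    if spec.zeta > 0.0:
        value -= spec.zeta * _logdet_pd(model.factor_corr, "factor_corr")
    return value


def is_perfect_simple(
    loadings: np.ndarray, tol: float = ZERO_TOL
) -> tuple[bool, list[int | None]]:
    """Check the perfect-simple-structure property (<= 1 nonzero per row).

    Returns ``(flag, columns)`` where ``columns[i]`` is the index of row i's
    surviving column, or ``None`` for an all-zero row.  For rows with more
    than one entry above ``tol`` the flag is False and the column entry is
    the argmax of ``|lambda|`` (informational only).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    flag = True
    cols: list[int | None] = []
    for row in np.abs(L):
        nz = np.flatnonzero(row > tol)
        if nz.size == 0:
            cols.append(None)
        elif nz.size == 1:
            cols.append(int(nz[0]))
        else:
            flag = False
            cols.append(int(np.argmax(row)))
    return flag, cols
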