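"""Penalty functions on factor loading matrices.

The prenet ("product-based elastic net") penalty acts on within-row *pairs*
of loadings,

    P(L) = sum_i sum_{j<k} { g |l_ij l_ik| + (1-g)/2 (l_ij l_ik)^2 },

so it vanishes whenever each row has at most one nonzero entry (a perfect
simple structure), in contrast with element-wise penalties (lasso, elastic
net, MCP) that vanish only at the zero matrix.  As g -> 0 the prenet tends
to half the quartimin rotation criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np

__all__ = [
    "PenaltySpec",
    "prenet_penalty",
    "quartimin_criterion",
    "elastic_net_penalty",
    "lasso_penalty",
    "mcp_penalty",
    "penalty_value",
]

_FAMILIES = ("prenet", "lasso", "enet", "mcp")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family plus its tuning parameters.

    Parameters
    ----------
    family : {"prenet", "lasso", "enet", "mcp"}
    gamma : float
        Mixing/concavity parameter.  prenet and enet require ``0 < gamma <= 1``
        (1 = pure L1-type part); mcp requires ``gamma > 1``; lasso ignores it.
    rho : float
        Regularization weight, ``>= 0``; ``math.inf`` requests the
        perfect-simple-structure (large-rho) mode.
    zeta : float
        Weight of the ``-zeta * log|Phi|`` factor-correlation stabilizer
        added to the reported objective (0 disables it).
    """

    family: str
    gamma: float = 1.0
    rho: float = 0.0
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.family in ("prenet", "enet") and not (0.0 < self.gamma <= 1.0):
            raise ValueError(
                f"{self.family} requires gamma in (0, 1], got {self.gamma}"
            )
        if self.family == "mcp" and not self.gamma > 1.0:
            raise ValueError(f"mcp requires gamma > 1, got {self.gamma}")
        if not (self.rho >= 0.0 or self.rho == inf):
            raise ValueError(f"rho must be >= 0 or inf, got {self.rho}")
        if self.zeta < 0.0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")

    @property
    def is_pss(self) -> bool:
        """True when rho = inf, i.e. perfect-simple-structure mode."""
        return self.rho == inf

    def with_rho(self, rho: float) -> "PenaltySpec":
        return PenaltySpec(self.family, self.gamma, rho, self.zeta)


def _check_gamma_unit(gamma: float) -> None:
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")


def prenet_penalty(loadings: np.ndarray, gamma: float) -> float:
    """Prenet penalty: sum_i sum_{j<k} g|l_ij l_ik| + (1-g)/2 (l_ij l_ik)^2."""
    _check_gamma_unit(gamma)
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D matrix")
    # sum over unordered pairs = (full cross sum - diagonal)/2, rowwise
    a = np.abs(L)
    abs_pairs = 0.5 * ((a.sum(axis=1) ** 2 - (a**2).sum(axis=1)).sum())
    sq = L**2
    sq_pairs = 0.5 * ((sq.sum(axis=1) ** 2 - (sq**2).sum(axis=1)).sum())
    return float(gamma * abs_pairs + 0.5 * (1.0 - gamma) * sq_pairs)


def quartimin_criterion(loadings: np.ndarray) -> float:
    """Quartimin rotation criterion: sum_i sum_{j<k} (l_ij l_ik)^2."""
    L = np.asarray(loadings, dtype=float)
    sq = L**2
    return float(0.5 * ((sq.sum(axis=1) ** 2 - (sq**2).sum(axis=1)).sum()))


def elastic_net_penalty(loadings: np.ndarray, gamma: float) -> float:
    """Elastic net: sum_ij g|l_ij| + (1-g)/2 l_ij^2; gamma=1 is the lasso."""
    _check_gamma_unit(gamma)
    L = np.asarray(loadings, dtype=float)
    return float(gamma * np.abs(L).sum() + 0.5 * (1.0 - gamma) * (L**2).sum())


def lasso_penalty(loadings: np.ndarray) -> float:
    """L1 penalty sum_ij |l_ij|."""
    return float(np.abs(np.asarray(loadings, dtype=float)).sum())


def mcp_penalty(loadings: np.ndarray, rho: float, gamma: float) -> float:
    """Minimax concave penalty, returned *already scaled by rho*.

    Per element: ``rho|l| - l^2/(2 gamma)`` for ``|l| <= rho*gamma``, and the
    saturated value ``rho^2 gamma / 2`` beyond.  Because rho enters the shape
    of the penalty itself, the total includes the rho factor; callers must not
    multiply by rho again.
    """
    if gamma <= 1.0:
        raise ValueError(f"mcp requires gamma > 1, got {gamma}")
    if rho < 0.0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    a = np.abs(np.asarray(loadings, dtype=float))
    inner = rho * a - a**2 / (2.0 * gamma)
    sat = 0.5 * rho**2 * gamma
    return float(np.where(a <= rho * gamma, inner, sat).sum())


def penalty_value(loadings: np.ndarray, spec: PenaltySpec) -> float:
    """rho-scaled penalty term of the objective for any family.

    For prenet/lasso/enet this is ``rho * P(L)``; for mcp the rho-scaled
    total is returned directly.  rho = inf (PSS mode) is rejected — the
    large-rho solver never evaluates the penalty.
    """
    if spec.is_pss:
        raise ValueError("penalty_value is undefined for rho = inf (PSS mode)")
    if spec.family == "prenet":
        return spec.rho * prenet_penalty(loadings, spec.gamma)
    if spec.family == "lasso":
        return spec.rho * lasso_penalty(loadings)
    if spec.family == "enet":
        return spec.rho * elastic_net_penalty(loadings, spec.gamma)
    return mcp_penalty(loadings, spec.rho, spec.gamma)
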