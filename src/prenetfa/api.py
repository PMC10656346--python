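"""Model/results interface for prenet-penalized factor analysis.

``PrenetFactor`` is constructed from a data table or a sample covariance
matrix; its ``fit`` / ``fit_pss`` / ``fit_path`` methods return results
objects carrying the estimates, diagnostics and a text ``summary()``.

Example
-------
>>> from prenetfa import PrenetFactor
>>> from prenetfa.simulate import make_model, sample_data
>>> X, _ = sample_data(make_model("A-ORT"), 500, seed=0)
>>> res = PrenetFactor(X, n_factors=4).fit_path(criterion="bic").selected
>>> res.n_effective_factors
4
"""

from __future__ import annotations

from math import inf

import numpy as np
import pandas as pd

from .clustering import VariablePartition, clusters_from_loadings
from .em import FitResult, cold_start, fit_em, fit_pss
from .model import FactorModel, SampleCov
from .path import (
    PathResult,
    cross_validate,
    effective_factors,
    select_model,
    solution_path,
)
from .penalties import PenaltySpec

__all__ = ["PrenetFactor", "FactorResults", "PathResults"]


class PrenetFactor:
    """Penalized maximum-likelihood factor model.

    Parameters
    ----------
    data : array-like of shape (n, p), optional
        Observations (rows).  Either ``data`` or ``cov`` must be given.
    n_factors : int
        Number of common factors m.
    cov : SampleCov or (p, p) array-like, optional
        Sample covariance in place of raw data; requires ``n_obs`` unless a
        :class:`SampleCov` is passed.
    n_obs : int, optional
        Sample size behind ``cov``.
    penalty : {"prenet", "lasso", "enet", "mcp"}
    gamma : float
        Penalty mixing/concavity parameter (see :class:`PenaltySpec`).
    zeta : float
        Weight of the factor-correlation stabilizer.
    orientation : {"orthogonal", "oblique"}
    standardize : bool
        Analyze the correlation matrix of ``data`` (ignored for ``cov``).
    var_names : sequence of str, optional
    """

    def __init__(
        self,
        data=None,
        n_factors: int = 1,
        *,
        cov=None,
        n_obs: int | None = None,
        penalty: str = "prenet",
        gamma: float = 1.0,
        zeta: float = 0.0,
        orientation: str = "orthogonal",
        standardize: bool = False,
        var_names=None,
    ) -> None:
        if (data is None) == (cov is None):
            raise ValueError("provide exactly one of data or cov")
        if data is not None:
            data = np.asarray(data, dtype=float)
            self.sample_cov = SampleCov.from_data(data, standardize=standardize)
            self.data = data
        else:
            self.data = None
            if isinstance(cov, SampleCov):
                self.sample_cov = cov
            else:
                if n_obs is None:
                    raise ValueError("cov input requires n_obs")
                self.sample_cov = SampleCov(np.asarray(cov, dtype=float), n_obs)
        self.n_factors = int(n_factors)
        self.orientation = orientation
        self.penalty_family = penalty
        self.gamma = float(gamma)
        self.zeta = float(zeta)
        p = self.sample_cov.p
        self.var_names = (
            [str(v) for v in var_names] if var_names is not None
            else [f"V{i + 1}" for i in range(p)]
        )
        if len(self.var_names) != p:
            raise ValueError("var_names length does not match p")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_factors: int, **kwargs):
        return cls(
            df.to_numpy(dtype=float), n_factors,
            var_names=list(df.columns), **kwargs,
        )

    def _spec(self, rho: float) -> PenaltySpec:
        return PenaltySpec(self.penalty_family, self.gamma, rho, self.zeta)

    def fit(
        self,
        rho: float,
        init: FactorModel | None = None,
        n_starts: int = 10,
        seed: int | None = 0,
        tol: float = 1e-7,
        max_iter: int = 1000,
    ) -> "FactorResults":
        """Fit at a fixed rho (rho = math.inf gives the PSS fit)."""
        if rho == inf:
            return self.fit_pss(n_starts=n_starts, seed=seed, tol=tol,
                                max_iter=max_iter)
        spec = self._spec(rho)
        rng = np.random.default_rng(seed)
        if init is not None:
            fit = fit_em(self.sample_cov, init, spec, tol=tol, max_iter=max_iter)
        else:
            fit = None
            for _ in range(max(1, n_starts)):
                start = cold_start(self.sample_cov, self.n_factors, rng,
                                   self.orientation)
                cand = fit_em(self.sample_cov, start, spec, tol=tol,
                              max_iter=max_iter)
                if fit is None or cand.objective < fit.objective:
                    fit = cand
        return FactorResults(self, fit)

    def fit_pss(
        self,
        n_starts: int = 10,
        seed: int | None = 0,
        tol: float = 1e-7,
        max_iter: int = 1000,
    ) -> "FactorResults":
        """Perfect-simple-structure fit (rho -> infinity); clusters variables."""
        fit = fit_pss(
            self.sample_cov, self.n_factors, n_starts=n_starts, seed=seed,
            orientation=self.orientation, tol=tol, max_iter=max_iter,
        )
        return FactorResults(self, fit)

    def fit_path(
        self,
        criterion: str | None = "bic",
        K: int = 30,
        delta: float = 0.001,
        start_mode: str = "warm",
        n_starts: int = 10,
        seed: int | None = 0,
        tol: float = 1e-7,
        max_iter: int = 1000,
    ) -> "PathResults":
        """Fit the whole decreasing-rho path; optionally pre-select by criterion."""
        path = solution_path(
            self.sample_cov, self.n_factors, self._spec(0.0), K=K, delta=delta,
            start_mode=start_mode, n_starts=n_starts, seed=seed,
            orientation=self.orientation, tol=tol, max_iter=max_iter,
        )
        return PathResults(self, path, criterion=criterion)

    def fit_cv(self, folds: int = 10, seed: int = 0, **path_kwargs):
        """Tenfold-style cross-validation of rho on raw data; returns
        (rho, grid, mean held-out discrepancies)."""
        if self.data is None:
            raise ValueError("cross-validation requires raw data, not a covariance")
        return cross_validate(
            self.data, self.n_factors, self._spec(0.0), folds=folds,
            seed=seed, orientation=self.orientation, **path_kwargs,
        )


class FactorResults:
    """Estimates and diagnostics of one penalized factor-analysis fit."""

    def __init__(self, model: PrenetFactor, fit: FitResult) -> None:
        self.model = model
        self.fit = fit

    @property
    def loadings(self) -> pd.DataFrame:
        m = self.fit.model.m
        return pd.DataFrame(
            self.fit.model.loadings,
            index=self.model.var_names,
            columns=[f"F{j + 1}" for j in range(m)],
        )

    @property
    def uniquenesses(self) -> pd.Series:
        return pd.Series(self.fit.model.uniquenesses, index=self.model.var_names)

    @property
    def factor_corr(self) -> pd.DataFrame:
        m = self.fit.model.m
        cols = [f"F{j + 1}" for j in range(m)]
        return pd.DataFrame(self.fit.model.factor_corr, index=cols, columns=cols)

    @property
    def objective(self) -> float:
        return self.fit.objective

    @property
    def discrepancy(self) -> float:
        return self.fit.discrepancy

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def n_effective_factors(self) -> int:
        return effective_factors(self.fit.model.loadings)

    def clusters(self, mode: str | None = None) -> VariablePartition:
        """Variable partition from the loadings (pss if possible, else argmax)."""
        from .model import is_perfect_simple

        if mode is None:
            mode = "pss" if is_perfect_simple(self.fit.model.loadings)[0] else "argmax"
        return clusters_from_loadings(self.fit.model.loadings, mode)

    def summary(self) -> str:
        fit = self.fit
        rho = fit.spec.rho if fit.spec is not None else float("nan")
        lines = [
            "Prenet-penalized factor analysis",
            "=" * 48,
            f"variables: {fit.model.p}    factors: {fit.model.m} "
            f"(effective {self.n_effective_factors})",
            f"orientation: {fit.model.orientation}",
            f"penalty: {fit.spec.family if fit.spec else '?'}  "
            f"gamma={fit.spec.gamma if fit.spec else '?'}  rho={rho:g}",
            f"objective: {fit.objective:.6f}   discrepancy: {fit.discrepancy:.6f}",
            f"iterations: {fit.n_iterations}   converged: {fit.converged}",
            f"nonzero loadings: {int((np.abs(fit.model.loadings) > 1e-10).sum())}"
            f" / {fit.model.p * fit.model.m}",
            "",
            "Loadings (|value| < 0.001 left blank):",
        ]
        L = self.loadings
        with pd.option_context("display.float_format", "{:8.3f}".format):
            txt = L.where(L.abs() >= 0.001).to_string(na_rep="        ")
        lines.append(txt)
        return "\n".join(lines)


class PathResults:
    """A fitted regularization path plus criterion-based selection."""

    def __init__(self, model: PrenetFactor, path: PathResult,
                 criterion: str | None = "bic") -> None:
        self.model = model
        self.path = path
        self.criterion = criterion

    @property
    def selected(self) -> FactorResults:
        fit, _ = select_model(self.path, self.criterion or "bic")
        return FactorResults(self.model, fit)

    def select(self, criterion: str = "bic") -> FactorResults:
        fit, _ = select_model(self.path, criterion)
        return FactorResults(self.model, fit)

    def to_frame(self) -> pd.DataFrame:
        return self.path.to_frame()

    def summary(self) -> str:
        df = self.to_frame()
        sel_idx = int(np.argmin(
            {"aic": self.path.aic, "bic": self.path.bic}[self.criterion or "bic"]
        ))
        header = (
            f"Regularization path: {self.path.family} gamma={self.path.gamma} "
            f"({self.path.start_mode} start, K={len(self.path)})\n"
            f"selected by {self.criterion or 'bic'}: "
            f"rho = {self.path.rho_grid[sel_idx]:.6g}\n"
        )
        with pd.option_context("display.float_format", "{:10.4f}".format):
            return header + df.to_string(index=False)
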