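"""Delimited-text input/output for data tables, fits and path results."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SampleCov

__all__ = ["load_table", "save_fit"]

logger = logging.getLogger(__name__)


def _read_delimited(path) -> pd.DataFrame:
    # sniff comma / tab / semicolon; first row may be a header
    df = pd.read_csv(path, sep=None, engine="python")
    cols = list(df.columns)
    try:
        numeric_header = [float(c) for c in cols]
    except (TypeError, ValueError):
        return df  # genuine (non-numeric) header
    # a numeric first row is data, except for pandas' default header 0..p-1
    if numeric_header == list(map(float, range(len(cols)))):
        df.columns = [f"V{i + 1}" for i in range(df.shape[1])]
        return df
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    df.columns = [f"V{i + 1}" for i in range(df.shape[1])]
    return df


def load_table(
    path,
    covariance: bool = False,
    n: int | None = None,
    standardize: bool = False,
):
    """Read a delimited numeric table.

    Returns ``(X, names)`` for raw data (optionally column-standardized), or
    a :class:`SampleCov` when ``covariance=True`` (then ``n`` is required
    and the matrix must be square symmetric).  Non-numeric cells raise with
    their row/column coordinates.
    """
    df = _read_delimited(path)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any() and df.notna().all().all():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric cell at row {r + 1}, column {df.columns[c]!r} in {path}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing or non-numeric cell at row {r + 1}, column "
            f"{df.columns[c]!r} in {path}"
        )
    names = [str(c) for c in df.columns]
    if covariance:
        if values.shape[0] != values.shape[1]:
            raise ValueError(
                f"covariance input must be square, got {values.shape}"
            )
        if n is None:
            raise ValueError("covariance input requires the sample size n")
        return SampleCov(values, n), names
    if standardize:
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    return values, names


def save_fit(
    out_dir,
    fit=None,
    partition=None,
    path_result=None,
    config: dict | None = None,
    var_names: list[str] | None = None,
) -> dict[str, Path]:
    """Write fit components as CSV plus a JSON run manifest.

    Writes whichever of loadings/Phi/Psi (from ``fit``), the cluster
    partition, and the path table are provided; returns the mapping of
    artifact name to file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if fit is not None:
        model = fit.model
        names = var_names or [f"V{i + 1}" for i in range(model.p)]
        cols = [f"F{j + 1}" for j in range(model.m)]
        pd.DataFrame(model.loadings, index=names, columns=cols).to_csv(
            out / "loadings.csv"
        )
        written["loadings"] = out / "loadings.csv"
        pd.DataFrame(model.factor_corr, index=cols, columns=cols).to_csv(
            out / "factor_corr.csv"
        )
        written["factor_corr"] = out / "factor_corr.csv"
        pd.DataFrame({"variable": names, "uniqueness": model.uniquenesses}).to_csv(
            out / "uniquenesses.csv", index=False
        )
        written["uniquenesses"] = out / "uniquenesses.csv"
    if partition is not None:
        dfp = partition.to_frame()
        if var_names is not None:
            dfp["variable"] = var_names
        dfp.to_csv(out / "clusters.csv", index=False)
        written["clusters"] = out / "clusters.csv"
    if path_result is not None:
        path_result.to_frame().to_csv(out / "path.csv", index=False)
        written["path"] = out / "path.csv"
    manifest = dict(config or {})
    if fit is not None:
        manifest.update(
            objective=fit.objective,
            converged=bool(fit.converged),
            n_iterations=int(fit.n_iterations),
            n_psi_floor_hits=int(fit.n_psi_floor_hits),
        )
    import prenetfa

    manifest["prenetfa_version"] = prenetfa.__version__
    manifest["numpy_version"] = np.__version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = out / "manifest.json"
    return written
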