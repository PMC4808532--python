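"""File I/O for the screening tool: delimited-text matrices and run manifests."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MethylationMatrix

__all__ = ["load_methylation", "load_covariates", "write_methylation", "write_manifest"]


def load_methylation(
    path: str | Path,
    sep: str | None = None,
    impute: str | None = None,
) -> MethylationMatrix:
    """Load a sites x samples M-value matrix from delimited text.

    First column: site ids; header row: sample ids. Duplicate site ids and
    non-numeric cells are errors. Missing values are rejected unless
    ``impute="mean"``, which replaces each missing cell with its site's row
    mean.
    """
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate site id(s) in {path}: {', '.join(map(str, sorted(set(dup))))}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric M-value cell in {path}: {exc}") from None
    if np.isnan(values).any():
        if impute == "mean":
            row_means = np.nanmean(values, axis=1, keepdims=True)
            values = np.where(np.isnan(values), row_means, values)
        else:
            n_missing = int(np.isnan(values).sum())
            raise ValueError(
                f"{n_missing} missing M-value(s) in {path}; pass impute='mean' to row-mean impute"
            )
    return MethylationMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def load_covariates(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Load the samples x covariates table (first column: sample ids)."""
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample id(s) in {path}")
    return df


def write_methylation(M: MethylationMatrix, path: str | Path, sep: str = "\t") -> None:
    M.to_dataframe().to_csv(path, sep=sep, index_label="site_id")


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Write a JSON run manifest (options, seed, versions) for reproducibility."""
    versions = {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    try:
        from importlib.metadata import version

        versions["ttscreen"] = version("ttscreen")
    except Exception:
        pass
    payload = dict(manifest)
    payload["versions"] = versions
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
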