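"""Delimited-text readers and writers for datasets and fit results.

"Machines" are in-process shards: a dataset on disk is an X table, a Y
column and (optionally) a machine-assignment column.  No network layer is
involved; the communication ledger in a fit result counts the vectors that
would be transmitted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .objective import DistributedDataset

__all__ = ["load_delimited_dataset", "write_dataset", "write_fit_result"]


def _read_numeric_table(path, name: str) -> np.ndarray:
    """Read a CSV/TSV of numbers (header optional, delimiter sniffed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} file not found: {path}")
    with open(path) as fh:
        first_line = fh.readline()
    sep = "\t" if "\t" in first_line else ";" if ";" in first_line else ","
    df = pd.read_csv(path, sep=sep, header=None)
    # header row: first row non-numeric, the rest numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = pd.read_csv(path, sep=sep, header=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"{name}: non-numeric or missing cell at row {r + 1}, column {c + 1} "
            f"({len(bad)} bad cells total)"
        )
    return numeric.to_numpy(dtype=float)


def load_delimited_dataset(x_path, y_path, shard_column_or_m) -> DistributedDataset:
    """Load X and Y from delimited text and shard them.

    ``shard_column_or_m``: either an integer machine count (rows are dealt
    round-robin, row i to machine i mod m) or a path to a one-column
    assignment file giving each row's machine id.
    """
    X = _read_numeric_table(x_path, "X")
    Y = _read_numeric_table(y_path, "Y").ravel()
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]} rows")
    if isinstance(shard_column_or_m, (int, np.integer)):
        m = int(shard_column_or_m)
        assignment = np.arange(X.shape[0]) % m
    else:
        assignment = _read_numeric_table(shard_column_or_m, "shard assignment").ravel()
        if assignment.shape[0] != X.shape[0]:
            raise ValueError(
                f"assignment has {assignment.shape[0]} rows but X has {X.shape[0]}"
            )
        assignment = assignment.astype(int)
    return DistributedDataset.from_arrays(X, Y, assignment=assignment)


def write_dataset(dataset: DistributedDataset, out_dir, prefix: str = "data") -> dict:
    """Write a dataset as X.csv, Y.csv and a shard-assignment column."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = np.concatenate([s.X for s in dataset.shards])
    Y = np.concatenate([s.Y for s in dataset.shards])
    shard_ids = np.concatenate(
        [np.full(s.n, s.machine_id if s.machine_id else j + 1, dtype=int)
         for j, s in enumerate(dataset.shards)]
    )
    paths = {
        "x": out / f"{prefix}_X.csv",
        "y": out / f"{prefix}_Y.csv",
        "shards": out / f"{prefix}_shards.csv",
    }
    pd.DataFrame(X).to_csv(paths["x"], index=False, header=False)
    pd.DataFrame(Y).to_csv(paths["y"], index=False, header=False)
    pd.DataFrame(shard_ids).to_csv(paths["shards"], index=False, header=False)
    return {k: str(v) for k, v in paths.items()}


def write_fit_result(fit, out_dir, run_config: dict = None, prefix: str = "fit") -> dict:
    """Serialise a FitResult to JSON plus a 1-indexed coefficient CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = fit.to_dict()
    if run_config is not None:
        payload["run_config"] = run_config
    json_path = out / f"{prefix}.json"
    json_path.write_text(json.dumps(payload, indent=2, default=str))
    coef = pd.DataFrame(
        {"j": np.arange(1, fit.beta.size + 1), "beta": fit.beta}
    )
    csv_path = out / f"{prefix}_coefficients.csv"
    coef.to_csv(csv_path, index=False)
    return {"json": str(json_path), "coefficients": str(csv_path)}
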