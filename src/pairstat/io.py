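"""Delimited-text input and output for matrices and result bundles."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import MixedMatrix, ResultBundle, validate_matrix

__all__ = ["read_matrix", "write_matrix", "write_bundle"]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path, kind: str, na_value: float = float("nan"),
                feature_axis: str = "rows", delimiter: str | None = None,
                na_token: str = "NA", header: bool = True,
                index: bool = True) -> MixedMatrix:
    """Read a delimited numeric matrix into a validated :class:`MixedMatrix`.

    The optional header row carries sample names and the optional first
    column feature names (for ``feature_axis="columns"`` the roles swap).
    Cells equal to ``na_token`` (or empty) map to ``na_value``; any other
    non-numeric cell is an error naming its coordinates, as is a ragged row.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    rows = [line.rstrip("\n").split(sep) for line in path.read_text().splitlines()
            if line.strip() != ""]
    if not rows:
        raise ValueError(f"{path}: empty file")
    col_names = None
    if header:
        col_names = rows[0][1:] if index else rows[0]
        rows = rows[1:]
    row_names = None
    if index:
        row_names = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    values = np.empty((len(rows), width), dtype=float)
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row at line {i + 1 + int(header)} "
                             f"({len(r)} fields, expected {width})")
        for j, cell in enumerate(r):
            cell = cell.strip()
            if cell == na_token or cell == "":
                values[i, j] = na_value
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(f"{path}: non-numeric cell {cell!r} at row "
                                     f"{i + 1}, column {j + 1}") from None
    if feature_axis == "rows":
        fnames, snames = row_names, col_names
    else:
        fnames, snames = col_names, row_names
    return validate_matrix(values, kind=kind, na_value=na_value,
                           feature_axis=feature_axis,
                           feature_names=fnames, sample_names=snames)


def _frame(matrix: np.ndarray, row_names, col_names) -> pd.DataFrame:
    F, S = matrix.shape
    rows = row_names if row_names is not None else [f"f{i}" for i in range(F)]
    cols = col_names if col_names is not None else [f"s{j}" for j in range(S)]
    return pd.DataFrame(matrix, index=rows, columns=cols)


def write_matrix(M: MixedMatrix, path, na_token: str = "NA",
                 delimiter: str | None = None) -> None:
    """Write a matrix as delimited text with missing entries as ``na_token``."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    values = M.values_with_nan()
    cols = M.sample_names if M.sample_names is not None else [f"s{j}" for j in range(M.n_samples)]
    _frame(values, M.feature_names, cols).to_csv(path, sep=sep, na_rep=na_token)


def write_bundle(bundle: ResultBundle, out_prefix, na_token: str = "",
                 extra_meta: dict | None = None) -> list[Path]:
    """Write one CSV per result matrix plus a JSON run-metadata sidecar.

    Files are named ``<prefix>_<result-name>.csv``; NaN cells (including the
    self-test diagonal of adjusted homogeneous matrices) are written as
    ``na_token`` (empty by default).
    """
    if not bundle.matrices:
        raise ValueError("cannot write an empty result bundle")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, matrix in bundle.items():
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        _frame(np.asarray(matrix, dtype=float), bundle.row_names,
               bundle.col_names).to_csv(out, na_rep=na_token)
        written.append(out)
    meta = {
        "test": bundle.test,
        "homogeneous": bundle.homogeneous,
        "outputs": list(bundle.keys()),
        "shape": list(np.asarray(next(iter(bundle.matrices.values()))).shape),
        "written_at": datetime.now(timezone.utc).isoformat(),
        **bundle.meta,
    }
    if extra_meta:
        meta.update(extra_meta)
    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    written.append(meta_path)
    return written


def read_result_matrix(path, na_token: str = "") -> np.ndarray:
    """Read back a bundle CSV written by :func:`write_bundle` (NaN-aware)."""
    df = pd.read_csv(path, index_col=0, na_values=[na_token] if na_token else None,
                     keep_default_na=True)
    return df.to_numpy(dtype=float)
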