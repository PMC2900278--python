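"""Tab-delimited readers and writers for expression, measurement and design matrices.

All matrices are genes-as-rows (designs: pools-as-rows) with a header
row of column labels and row identifiers in the first column.  A header
comment line ``# scale=linear`` or ``# scale=log2`` declares the
intensity scale of expression/measurement files; a file without the
declaration is treated as log2 (the convention of published
log-transformed expression tables) with a logged warning.  Tab is the
only delimiter, UTF-8, "." decimal separator.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .design import PoolingDesign

__all__ = ["MatrixFile", "read_matrix", "write_matrix", "read_design", "write_design"]

logger = logging.getLogger("poolmc")

Kind = Literal["expression", "measurement", "design"]


@dataclass
class MatrixFile:
    """A parsed matrix file: values plus declared kind and scale."""

    frame: pd.DataFrame
    kind: Kind
    scale: Literal["linear", "log2"] | None
    path: str | None = None


def _parse_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse a tab-delimited table, collecting leading ``# key=value`` comments.

    Raises ValueError with a 1-based line number on ragged rows,
    non-numeric cells, or duplicate row identifiers.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells[1:]
                continue
            if len(cells) != len(header) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row — expected {len(header) + 1} "
                    f"columns, found {len(cells)}"
                )
            ids.append(cells[0])
            parsed = []
            for col, cell in enumerate(cells[1:], start=2):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column {col}"
                    ) from None
            rows.append(parsed)
    if header is None:
        raise ValueError(f"{path}: empty file (no header row)")
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate row identifiers: {sorted(set(dupes))[:5]}")
    frame = pd.DataFrame(np.array(rows, dtype=float).reshape(len(ids), len(header)),
                         index=pd.Index(ids, name="id"), columns=header)
    return frame, meta


def read_matrix(path: str | Path, kind: Kind = "expression") -> MatrixFile:
    """Read and validate a tab-delimited matrix file.

    Designs must be strictly binary; linear-scale expression and
    measurement values must be nonnegative.  Duplicate row identifiers,
    ragged rows and non-numeric cells are rejected with line numbers.
    """
    frame, meta = _parse_table(path)
    if kind == "design":
        vals = frame.to_numpy()
        if not np.isin(np.unique(vals), (0.0, 1.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0))])
            raise ValueError(f"{path}: design matrix must be binary; found values {bad[:5]}")
        return MatrixFile(frame=frame.astype(np.int8), kind=kind, scale=None, path=str(path))
    scale = meta.get("scale")
    if scale is None:
        logger.warning("%s: no '# scale=' declaration; assuming log2", path)
        scale = "log2"
    if scale not in ("linear", "log2"):
        raise ValueError(f"{path}: unknown scale declaration {scale!r}")
    if scale == "linear" and (frame.to_numpy() < 0).any():
        raise ValueError(f"{path}: linear-scale intensities must be nonnegative")
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    return MatrixFile(frame=frame, kind=kind, scale=scale, path=str(path))  # type: ignore[arg-type]


def write_matrix(
    frame: pd.DataFrame,
    path: str | Path,
    kind: Kind = "expression",
    scale: Literal["linear", "log2"] | None = "linear",
) -> None:
    """Write a matrix as tab-delimited text with a scale declaration.

    Values are written with full float precision so that
    ``read_matrix(write_matrix(M))`` reproduces M exactly, preserving
    row/column order and labels.
    """
    buf = _io.StringIO()
    if kind != "design" and scale is not None:
        buf.write(f"# scale={scale}\n")
    if kind == "design":
        out = frame.astype(int)
    else:
        out = frame
    out.to_csv(buf, sep="\t", index_label=frame.index.name or "id")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_design(path: str | Path) -> PoolingDesign:
    """Read a pooling design file into a validated :class:`PoolingDesign`."""
    mf = read_matrix(path, kind="design")
    colsums = np.unique(mf.frame.to_numpy().sum(axis=0))
    if len(colsums) != 1:
        raise ValueError(
            f"{path}: columns have unequal degrees {colsums.tolist()}; "
            "a pooling design must be left-regular"
        )
    return PoolingDesign(
        matrix=mf.frame.to_numpy(),
        left_degree=int(colsums[0]),
        sample_labels=[str(c) for c in mf.frame.columns],
        pool_labels=[str(i) for i in mf.frame.index],
    )


def write_design(design: PoolingDesign, path: str | Path) -> None:
    """Write a pooling design as a 0/1 tab-delimited table."""
    frame = pd.DataFrame(
        design.matrix,
        index=pd.Index(design.pool_labels, name="pool"),
        columns=design.sample_labels,
    )
    write_matrix(frame, path, kind="design", scale=None)
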