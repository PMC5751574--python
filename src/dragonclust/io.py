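"""Delimited-text I/O for sample matrices and label vectors."""

from __future__ import annotations

import csv
import hashlib
import logging
from pathlib import Path

import numpy as np

from .mlcore import InvalidInputError

logger = logging.getLogger(__name__)


def file_checksum(path) -> str:
    """sha256 of the raw file bytes, for run-report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_matrix(
    path,
    delimiter: str = "\t",
    transpose: bool = False,
    header: bool = False,
) -> np.ndarray:
    """Read a numeric samples × features matrix from delimited text.

    ``header=True`` skips the first row (and, if the remaining rows carry one
    extra leading field, that first column too — the usual layout of a table
    with both row and column names).  ``transpose=True`` flips the matrix
    after reading, for genes × samples tables.  Errors name the offending
    cell by 1-based line and column.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        raw = [(lineno, row) for lineno, row in
               enumerate(csv.reader(fh, delimiter=delimiter), start=1) if row]
    if not raw:
        raise InvalidInputError(f"{path}: empty matrix file")
    if header:
        ncols_header = len(raw[0][1])
        raw = raw[1:]
        if not raw:
            raise InvalidInputError(f"{path}: matrix file has only a header row")
        if len(raw[0][1]) == ncols_header + 1:
            raw = [(lineno, row[1:]) for lineno, row in raw]
    width = len(raw[0][1])
    data = np.empty((len(raw), width), dtype=float)
    for i, (lineno, row) in enumerate(raw):
        if len(row) != width:
            raise InvalidInputError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise InvalidInputError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, column {j + 1}"
                ) from None
    if transpose:
        data = data.T
    logger.info(
        "loaded %s: %d samples x %d features (sha256 %s)",
        path, data.shape[0], data.shape[1], file_checksum(path)[:12],
    )
    return data


def load_labels(path) -> np.ndarray:
    """Read one label per line (integer or string; blank lines ignored)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    labels = [ln for ln in lines if ln]
    if not labels:
        raise InvalidInputError(f"{path}: empty label file")
    try:
        return np.asarray([int(x) for x in labels])
    except ValueError:
        return np.asarray(labels)


def write_matrix(path, X: np.ndarray, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(X), delimiter=delimiter, fmt="%.10g")


def write_labels(path, labels) -> None:
    Path(path).write_text("".join(f"{int(l)}\n" for l in np.asarray(labels).ravel()))
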