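"""Readers, writers and physical-scale conversion.

Input series are plain text (one sample per line) or a CSV column; outputs
are long-format tab-separated tables.  No binary formats.  Input series
must be fully numeric: blank lines, NaNs and non-numeric rows are rejected
with the offending line numbers, since editing (e.g. removal of premature
beats from an R-R series) belongs upstream of the analysis.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["read_series", "scale_axis", "write_surface", "read_surface"]

_SURFACE_COLUMNS = ["order", "q", "n", "tau", "value", "retained"]


def read_series(path, format: str | None = None,
                column: str | int | None = None) -> np.ndarray:
    """Read one univariate series from a text or CSV file.

    ``format`` is ``"txt"`` (one sample per line) or ``"csv"``; when None
    it is inferred from the extension (default txt).  ``column`` selects
    the CSV column by name or position; a lone unnamed column is used as
    is.

    Raises
    ------
    ValueError
        On blank lines, non-numeric rows (listing 1-based line numbers),
        NaN entries, or a missing column.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "csv" if ext == ".csv" else "txt"
    if format == "txt":
        return _read_txt(path)
    if format == "csv":
        return _read_csv(path, column)
    raise ValueError(f"unknown format {format!r}; use 'txt' or 'csv'")


def _read_txt(path) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":  # single trailing newline is fine
        lines.pop()
    values = np.empty(len(lines))
    bad: list[int] = []
    for k, line in enumerate(lines):
        try:
            values[k] = float(line)
        except ValueError:
            bad.append(k + 1)
            continue
        if not np.isfinite(values[k]):
            bad.append(k + 1)
    if bad:
        shown = ", ".join(map(str, bad[:20]))
        more = f" (+{len(bad) - 20} more)" if len(bad) > 20 else ""
        raise ValueError(
            f"{path}: {len(bad)} blank/non-numeric/non-finite line(s) at "
            f"line number(s) {shown}{more}")
    if values.size == 0:
        raise ValueError(f"{path}: empty file")
    return values


def _read_csv(path, column) -> np.ndarray:
    df = pd.read_csv(path, skip_blank_lines=False)
    if column is None:
        if df.shape[1] != 1:
            raise ValueError(
                f"{path}: {df.shape[1]} columns; specify which with "
                f"'column'")
        series = df.iloc[:, 0]
    elif isinstance(column, int):
        series = df.iloc[:, column]
    else:
        if column not in df.columns:
            raise ValueError(
                f"{path}: no column {column!r}; available: "
                f"{list(df.columns)}")
        series = df[column]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values))[0]
    if bad.size:
        # +2: 1-based plus the header row
        shown = ", ".join(str(b + 2) for b in bad[:20])
        more = f" (+{bad.size - 20} more)" if bad.size > 20 else ""
        raise ValueError(
            f"{path}: {bad.size} missing/non-numeric value(s) at "
            f"line number(s) {shown}{more}")
    return values


def scale_axis(n_grid, unit: str = "samples", mean_rr: float | None = None,
               fs: float | None = None) -> np.ndarray:
    """Convert block sizes to a physical time scale tau.

    ``unit``:

    * ``"samples"`` — tau = n (identity);
    * ``"rr"`` — beats to seconds, tau = n * mean_rr with ``mean_rr`` the
      mean R-R interval in seconds;
    * ``"hz"`` — samples to milliseconds, tau = n * 1000 / fs for sampling
      rate ``fs`` in Hz.
    """
    n = np.asarray(n_grid, dtype=float)
    if unit == "samples":
        return n.copy()
    if unit == "rr":
        if mean_rr is None or mean_rr <= 0:
            raise ValueError("unit='rr' needs a positive mean_rr (seconds)")
        return n * float(mean_rr)
    if unit == "hz":
        if fs is None or fs <= 0:
            raise ValueError("unit='hz' needs a positive sampling rate fs")
        return n * (1000.0 / float(fs))
    raise ValueError(f"unknown unit {unit!r}; use samples, rr or hz")


def write_surface(surface, path, tau: np.ndarray | None = None) -> None:
    """Write a fluctuation or alpha surface as a long-format TSV.

    Columns are {order, q, n, tau, value, retained} in that order; missing
    cells are the token ``NA``; values round-trip at full double
    precision.  Alpha surfaces have no retained counts (NA).
    """
    frame = surface.to_frame(tau=tau)
    if "F_normalized" in frame.columns:  # fluctuation surface
        frame = frame.rename(columns={"F_normalized": "value",
                                      "retained_blocks": "retained"})
    else:                                # alpha surface
        frame = frame.rename(columns={"alpha": "value"})
        frame["retained"] = pd.NA
    frame = frame[_SURFACE_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format=lambda v: repr(float(v)))


def read_surface(path) -> pd.DataFrame:
    """Read back a surface TSV written by :func:`write_surface`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       float_precision="round_trip")
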