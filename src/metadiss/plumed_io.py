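"""PLUMED-style COLVAR / HILLS text records.

Both dialects are plain whitespace-delimited columns with ``#``-prefixed
comment/header lines.  A COLVAR file carries ``time  cv``; a HILLS file
carries one deposited Gaussian per line as ``time  center  sigma  height``
(extra trailing columns, e.g. a bias factor, are ignored on read).
Times are in ps, the collective variable and sigma in nm, heights in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, FormatError

__all__ = [
    "CVSeries",
    "HillsRecord",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
]


@dataclass
class CVSeries:
    """A collective-variable time series (times in ps, values in CV units)."""

    times: np.ndarray
    values: np.ndarray
    name: str = "cv"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise FormatError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HillsRecord:
    """Ordered Gaussian bias depositions from a metadynamics run."""

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    cv_name: str = "cv"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        n = len(self.times)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise FormatError("hills columns must have equal length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise FormatError("hill times must be strictly increasing", line=bad + 1)
        if np.any(self.sigmas <= 0):
            raise FormatError("hill sigma must be positive")
        if np.any(self.heights < 0):
            raise FormatError("hill height must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


def _parse_columns(path, n_cols: int, what: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < n_cols:
                raise FormatError(
                    f"{what}: expected at least {n_cols} columns", line=lineno
                )
            try:
                rows.append(([float(p) for p in parts[:n_cols]], lineno))
            except ValueError as exc:
                raise FormatError(f"{what}: non-numeric field", line=lineno) from exc
    if not rows:
        raise EmptyInputError(f"{what}: no data lines in {path}")
    return rows


def read_colvar(path, name: str = "cv") -> CVSeries:
    """Read a two-column (time, cv) COLVAR-style file."""
    rows = _parse_columns(path, 2, "COLVAR")
    data = np.array([r[0] for r in rows])
    return CVSeries(times=data[:, 0], values=data[:, 1], name=name)


def write_colvar(series: CVSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {series.name}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.6f} {v:.9f}\n")


def read_hills(path, cv_name: str = "cv") -> HillsRecord:
    """Read a HILLS-style file with columns time, center, sigma, height.

    Monotonicity and positivity are validated; violations raise
    :class:`~metadiss.errors.FormatError` citing the offending line.
    """
    rows = _parse_columns(path, 4, "HILLS")
    data = np.array([r[0] for r in rows])
    linenos = [r[1] for r in rows]
    times = data[:, 0]
    if len(times) > 1:
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise FormatError(
                "hill times must be strictly increasing", line=linenos[int(bad[0]) + 1]
            )
    neg = np.flatnonzero(data[:, 2] <= 0)
    if neg.size:
        raise FormatError("hill sigma must be positive", line=linenos[int(neg[0])])
    return HillsRecord(
        times=times,
        centers=data[:, 1],
        sigmas=data[:, 2],
        heights=data[:, 3],
        cv_name=cv_name,
    )


def write_hills(hills: HillsRecord, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {hills.cv_name} sigma_{hills.cv_name} height\n")
        for t, c, s, h in zip(hills.times, hills.centers, hills.sigmas, hills.heights):
            fh.write(f"{t:.6f} {c:.9f} {s:.9f} {h:.9f}\n")
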