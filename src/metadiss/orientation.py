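"""Interdomain orientation metrics.

A reference structure defines, per domain, an origin (centroid of a core
atom selection) and two orthonormal axes (the first two principal axes of
the core coordinates, signs fixed deterministically).  For every frame the
reference frame of each domain is transported onto the observed pose by
least-squares rigid superposition of its core, and six metrics are read
off: the centre-axis length dC (chain-a origin to chain-b origin), four
tilt angles of the domain axes against the centre axis (AC1, AC2, BC1,
BC2) and the signed torsion AB between the planes (A1, C) and (C, B1),
right-handed about C pointing a -> b.  These are deterministic analogues
of the orientation descriptors used for antibody domain interfaces; they
are comparable within this package, not numerically identical to any
external tool's frame conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circstd

from .errors import DegenerateFrameError, InvalidParameterError, SelectionError

__all__ = [
    "DomainFrameDef",
    "OrientationMetrics",
    "define_reference_frames",
    "orientation_metrics",
    "orientation_timeseries",
    "variability_summary",
]

ANGLE_NAMES = ("AB", "AC1", "AC2", "BC1", "BC2")
METRIC_NAMES = ("dC",) + ANGLE_NAMES


@dataclass
class DomainFrameDef:
    chain_a: str
    chain_b: str
    core_a: np.ndarray  # residue ids
    core_b: np.ndarray
    ref_coords_a: np.ndarray  # core coordinates of the reference
    ref_coords_b: np.ndarray
    origin_a: np.ndarray
    origin_b: np.ndarray
    axes_a: np.ndarray  # (2, 3): A1, A2
    axes_b: np.ndarray  # (2, 3): B1, B2


@dataclass
class OrientationMetrics:
    dC: float
    AB: float
    AC1: float
    AC2: float
    BC1: float
    BC2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dC, self.AB, self.AC1, self.AC2, self.BC1, self.BC2])


def _core_coords(frame, chain: str, residues) -> np.ndarray:
    mask = frame.chain_id == chain
    if residues is not None:
        mask &= np.isin(frame.res_id, residues)
    if not mask.any():
        raise SelectionError(f"core selection empty for chain {chain!r}")
    return np.asarray(frame.coord[mask], dtype=np.float64)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-10 * max(evals[0], 1.0):
        raise DegenerateFrameError(
            "core coordinates are (nearly) collinear; need >= 3 non-collinear atoms"
        )
    return evecs.T[:2]  # rows: first, second principal axis


def _fix_signs(axes: np.ndarray, coords: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Deterministic axis signs: point toward the anchor atom (highest-
    numbered core residue); fall back to the largest-coordinate convention
    when the anchor is perpendicular to an axis."""
    out = axes.copy()
    rel = anchor - coords.mean(axis=0)
    for i in range(2):
        proj = float(np.dot(out[i], rel))
        if abs(proj) > 1e-8:
            if proj < 0:
                out[i] = -out[i]
        elif out[i][np.argmax(np.abs(out[i]))] < 0:
            out[i] = -out[i]
    return out


def define_reference_frames(
    reference,
    core_a=None,
    core_b=None,
    chain_a: str = "a",
    chain_b: str = "b",
) -> DomainFrameDef:
    """Build the per-domain coordinate systems on the reference structure.

    ``core_a``/``core_b`` are iterables of residue ids (default: all
    residues of the chain).  Axis signs point toward the highest-numbered
    core residue, so repeated calls are bit-for-bit identical.
    """
    frames = {}
    for chain, core in ((chain_a, core_a), (chain_b, core_b)):
        core_arr = None if core is None else np.asarray(list(core))
        coords = _core_coords(reference, chain, core_arr)
        if len(coords) < 3:
            raise DegenerateFrameError("need at least 3 core atoms per chain")
        axes = _principal_axes(coords)
        mask = reference.chain_id == chain
        if core_arr is not None:
            mask &= np.isin(reference.res_id, core_arr)
        last_res = reference.res_id[mask].max()
        anchor = reference.coord[mask & (reference.res_id == last_res)].mean(axis=0)
        frames[chain] = (coords, _fix_signs(axes, coords, anchor))
    coords_a, axes_a = frames[chain_a]
    coords_b, axes_b = frames[chain_b]
    return DomainFrameDef(
        chain_a=chain_a,
        chain_b=chain_b,
        core_a=np.unique(reference.res_id[reference.chain_id == chain_a])
        if core_a is None
        else np.asarray(list(core_a)),
        core_b=np.unique(reference.res_id[reference.chain_id == chain_b])
        if core_b is None
        else np.asarray(list(core_b)),
        ref_coords_a=coords_a,
        ref_coords_b=coords_b,
        origin_a=coords_a.mean(axis=0),
        origin_b=coords_b.mean(axis=0),
        axes_a=axes_a,
        axes_b=axes_b,
    )


def _kabsch(ref: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Optimal rotation R with obs_centered ~ ref_centered @ R.T."""
    p = ref - ref.mean(axis=0)
    q = obs - obs.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def orientation_metrics(frame, dfd: DomainFrameDef) -> OrientationMetrics:
    """The six metrics of one frame relative to the reference definition."""
    obs_a = _core_coords(frame, dfd.chain_a, dfd.core_a)
    obs_b = _core_coords(frame, dfd.chain_b, dfd.core_b)
    if obs_a.shape != dfd.ref_coords_a.shape or obs_b.shape != dfd.ref_coords_b.shape:
        raise InvalidParameterError("frame core selection does not match reference")
    r_a = _kabsch(dfd.ref_coords_a, obs_a)
    r_b = _kabsch(dfd.ref_coords_b, obs_b)
    a1, a2 = (r_a @ dfd.axes_a.T).T
    b1, b2 = (r_b @ dfd.axes_b.T).T
    origin_a = obs_a.mean(axis=0)
    origin_b = obs_b.mean(axis=0)
    c = origin_b - origin_a
    dc = float(np.linalg.norm(c))
    if dc < 1e-12:
        raise InvalidParameterError("domain origins coincide; centre axis undefined")
    c_hat = c / dc

    def tilt(v, axis):
        return float(
            np.degrees(np.arccos(np.clip(np.dot(v, axis), -1.0, 1.0)))
        )

    ac1, ac2 = tilt(a1, c_hat), tilt(a2, c_hat)
    bc1, bc2 = tilt(b1, -c_hat), tilt(b2, -c_hat)

    # signed dihedral between planes (A1, C) and (C, B1), right-handed about C
    n1 = a1 - np.dot(a1, c_hat) * c_hat
    n2 = b1 - np.dot(b1, c_hat) * c_hat
    ab = float(
        np.degrees(np.arctan2(np.dot(np.cross(n1, n2), c_hat), np.dot(n1, n2)))
    )
    if ab <= -180.0:
        ab += 360.0
    return OrientationMetrics(dC=dc, AB=ab, AC1=ac1, AC2=ac2, BC1=bc1, BC2=bc2)


def orientation_timeseries(traj, dfd: DomainFrameDef) -> pd.DataFrame:
    """Per-frame metrics as a DataFrame with columns dC, AB, AC1, AC2, BC1, BC2."""
    rows = [orientation_metrics(traj.frame(t), dfd).as_array() for t in range(traj.n_frames)]
    df = pd.DataFrame(rows, columns=METRIC_NAMES)
    df.insert(0, "frame", np.arange(traj.n_frames))
    return df


def variability_summary(
    metrics: pd.DataFrame, windows: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-window standard deviation of each metric.

    The torsion AB is circular (degrees, wrap at +-180) and uses the
    circular standard deviation; tilts and dC use the ordinary one.  The
    returned frame also flags, per window, the angle with the largest
    standard deviation (angles compare in degrees; dC is excluded as it is
    not an angle).
    """
    if windows is None:
        windows = np.array(["all"] * len(metrics))
    windows = np.asarray(windows)
    rows = []
    for window in pd.unique(windows):
        sub = metrics[windows == window]
        if len(sub) < 2:
            raise InvalidParameterError(
                f"window {window!r} has fewer than 2 frames"
            )
        row = {"window": window, "n_frames": len(sub)}
        for name in METRIC_NAMES:
            if name == "AB":
                row[f"sd_{name}"] = float(
                    np.degrees(circstd(np.radians(sub[name].to_numpy())))
                )
            else:
                row[f"sd_{name}"] = float(sub[name].std(ddof=1))
        angle_sds = {a: row[f"sd_{a}"] for a in ANGLE_NAMES}
        row["largest_variance_angle"] = max(angle_sds, key=angle_sds.get)
        rows.append(row)
    return pd.DataFrame(rows)
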