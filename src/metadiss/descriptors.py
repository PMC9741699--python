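"""Per-frame scalar descriptors of a two-chain complex.

Three descriptors drive the whole dissociation analysis: the distance
between the centres of mass of the two chains (the metadynamics collective
variable), the fraction of native inter-chain contacts Q relative to a
reference structure, and the solvent-accessible surface area (SASA).
Coordinates are Angstrom throughout; frame spacing is supplied by the
caller because trajectory formats do not reliably carry time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    RadiusTableError,
    SelectionError,
)

__all__ = [
    "Trajectory",
    "NativeContactSet",
    "DescriptorSeries",
    "load_trajectory",
    "com_distance",
    "define_native_contacts",
    "fraction_native_contacts",
    "sasa",
    "descriptor_timeseries",
    "write_descriptor_csv",
    "read_descriptor_csv",
]


@dataclass
class Trajectory:
    """Ordered coordinate snapshots sharing one topology.

    Wraps a :class:`biotite.structure.AtomArrayStack`; ``frame_spacing`` is
    the time per frame in ns.
    """

    stack: struc.AtomArrayStack
    frame_spacing: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def chain_ids(self) -> list[str]:
        return list(np.unique(self.stack.chain_id))

    def frame(self, i: int) -> struc.AtomArray:
        return self.stack[i]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing


@dataclass
class NativeContactSet:
    """Inter-chain residue pairs in contact in the reference structure."""

    pairs: list[tuple[int, int]]
    cutoff: float
    chain_a: str = "a"
    chain_b: str = "b"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DescriptorSeries:
    """A per-frame scalar series with units and time spacing."""

    name: str
    values: np.ndarray
    units: str
    frame_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_spacing


def _chain_mask(atoms, chain_id: str) -> np.ndarray:
    mask = atoms.chain_id == chain_id
    if not mask.any():
        available = sorted(set(atoms.chain_id))
        raise SelectionError(
            f"chain {chain_id!r} not present; available chains: {available}"
        )
    return mask


def load_trajectory(
    structure_path,
    trajectory_path=None,
    chain_a: str = "a",
    chain_b: str = "b",
    frame_spacing: float = 1.0,
) -> Trajectory:
    """Load a two-chain trajectory.

    ``structure_path`` is a (possibly multi-model) PDB file.  If
    ``trajectory_path`` is given it must be a DCD/XTC file readable by
    mdtraj, with the PDB serving as topology.  Only atoms of the two
    requested chains are kept.
    """
    structure_path = Path(structure_path)
    if trajectory_path is None:
        pdb = PDBFile.read(str(structure_path))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise EmptyInputError(f"{structure_path} contains no models")
        stack = pdb.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
    else:
        import mdtraj

        mt = mdtraj.load(str(trajectory_path), top=str(structure_path))
        if mt.n_frames == 0:
            raise EmptyInputError(f"{trajectory_path} contains no frames")
        pdb = PDBFile.read(str(structure_path))
        template = pdb.get_structure(model=1)
        stack = struc.AtomArrayStack(mt.n_frames, template.array_length())
        for category in template.get_annotation_categories():
            stack.set_annotation(category, template.get_annotation(category))
        stack.coord = mt.xyz * 10.0  # nm -> Angstrom

    mask = _chain_mask(stack, chain_a) | _chain_mask(stack, chain_b)
    stack = stack[..., mask]
    return Trajectory(stack=stack, frame_spacing=frame_spacing)


_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


def _masses(atoms) -> np.ndarray:
    out = np.empty(atoms.array_length())
    for i, element in enumerate(atoms.element):
        m = _MASSES.get(element.capitalize())
        if m is None:
            m = struc_info.mass(element, is_residue=False)
        out[i] = m if m is not None else 12.011
    return out


def com_distance(
    frame: struc.AtomArray,
    chain_a: str = "a",
    chain_b: str = "b",
    weighting: str = "mass",
) -> float:
    """Distance between the chain centroids (mass-weighted by default)."""
    if weighting not in ("mass", "geometric"):
        raise InvalidParameterError("weighting must be 'mass' or 'geometric'")
    centroids = []
    for chain in (chain_a, chain_b):
        mask = _chain_mask(frame, chain)
        coords = frame.coord[mask]
        if weighting == "mass":
            w = _masses(frame[mask])
            centroids.append((coords * w[:, None]).sum(axis=0) / w.sum())
        else:
            centroids.append(coords.mean(axis=0))
    return float(np.linalg.norm(centroids[1] - centroids[0]))


def _heavy_mask(atoms) -> np.ndarray:
    return atoms.element != "H"


def _min_residue_pair_distances(frame, chain_a, chain_b):
    """Minimum heavy-atom distance for every inter-chain residue pair.

    Returns (res_ids_a, res_ids_b, dmin) where dmin[i, j] is the minimum
    distance between residue res_ids_a[i] of chain a and res_ids_b[j] of
    chain b.
    """
    mask_a = _chain_mask(frame, chain_a) & _heavy_mask(frame)
    mask_b = _chain_mask(frame, chain_b) & _heavy_mask(frame)
    sub_a, sub_b = frame[mask_a], frame[mask_b]
    res_a, inv_a = np.unique(sub_a.res_id, return_inverse=True)
    res_b, inv_b = np.unique(sub_b.res_id, return_inverse=True)
    diff = sub_a.coord[:, None, :] - sub_b.coord[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    dmin = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(dmin, (inv_a[:, None], inv_b[None, :]), d)
    return res_a, res_b, dmin


def define_native_contacts(
    reference: struc.AtomArray,
    cutoff: float = 4.5,
    chain_a: str = "a",
    chain_b: str = "b",
) -> NativeContactSet:
    """All inter-chain residue pairs with min heavy-atom distance < cutoff."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    res_a, res_b, dmin = _min_residue_pair_distances(reference, chain_a, chain_b)
    ii, jj = np.nonzero(dmin < cutoff)
    pairs = [(int(res_a[i]), int(res_b[j])) for i, j in zip(ii, jj)]
    return NativeContactSet(pairs=pairs, cutoff=cutoff, chain_a=chain_a, chain_b=chain_b)


def fraction_native_contacts(frame: struc.AtomArray, native: NativeContactSet) -> float:
    """Share of native pairs still within the cutoff in this frame."""
    if len(native) == 0:
        raise InvalidParameterError("native contact set is empty")
    res_a, res_b, dmin = _min_residue_pair_distances(
        frame, native.chain_a, native.chain_b
    )
    idx_a = {r: i for i, r in enumerate(res_a)}
    idx_b = {r: i for i, r in enumerate(res_b)}
    formed = 0
    for ra, rb in native.pairs:
        if ra in idx_a and rb in idx_b and dmin[idx_a[ra], idx_b[rb]] < native.cutoff:
            formed += 1
    return formed / len(native)


def sasa(
    frame: struc.AtomArray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    per_chain: bool = False,
):
    """Shrake-Rupley style SASA in A^2 (total, or per chain).

    Uses element-wise van der Waals radii; hydrogens, if present, are
    ignored (heavy-atom-only mode).  Unknown elements raise a
    :class:`~metadiss.errors.RadiusTableError` naming the element.
    """
    heavy = frame[_heavy_mask(frame)]
    for element in np.unique(heavy.element):
        if struc_info.vdw_radius_single(element) is None:
            raise RadiusTableError(f"no van der Waals radius for element {element!r}")
    areas = struc.sasa(
        heavy,
        probe_radius=probe_radius,
        point_number=n_sphere_points,
        vdw_radii="Single",
    )
    areas = np.nan_to_num(areas)
    if per_chain:
        return {
            chain: float(areas[heavy.chain_id == chain].sum())
            for chain in np.unique(heavy.chain_id)
        }
    return float(areas.sum())


def descriptor_timeseries(
    traj: Trajectory,
    native: NativeContactSet,
    probe_radius: float = 1.4,
    sasa_points: int = 240,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> dict[str, DescriptorSeries]:
    """Compute the three descriptor series on a shared time axis.

    ``sasa_points`` trades SASA precision for speed; the default (240) keeps
    per-frame noise well below the bound-ensemble fluctuations the state
    model consumes.
    """
    chain_a = chain_a or native.chain_a
    chain_b = chain_b or native.chain_b
    com = np.empty(traj.n_frames)
    q = np.empty(traj.n_frames)
    area = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.frame(t)
        com[t] = com_distance(frame, chain_a, chain_b)
        q[t] = fraction_native_contacts(frame, native)
        area[t] = sasa(frame, probe_radius=probe_radius, n_sphere_points=sasa_points)
    fs = traj.frame_spacing
    return {
        "com_distance": DescriptorSeries("com_distance", com, "A", fs),
        "q_native": DescriptorSeries("q_native", q, "fraction", fs),
        "sasa": DescriptorSeries("sasa", area, "A^2", fs),
    }


def write_descriptor_csv(series: DescriptorSeries, path) -> None:
    df = pd.DataFrame(
        {"time_ns": series.times(), f"{series.name}_{series.units}": series.values}
    )
    df.to_csv(path, index=False)


def read_descriptor_csv(path) -> DescriptorSeries:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or len(df) == 0:
        raise EmptyInputError(f"{path}: no descriptor data")
    name_units = df.columns[1]
    name, _, units = name_units.rpartition("_")
    times = df.iloc[:, 0].to_numpy()
    spacing = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return DescriptorSeries(name or name_units, df.iloc[:, 1].to_numpy(), units, spacing)
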