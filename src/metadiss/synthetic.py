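"""Synthetic inputs: toy dimers, programmed dissociations, 1-D metadynamics.

Everything here is ground-truth-bearing test scaffolding for the analysis
modules: a two-chain pseudo-protein whose interface contacts are placed by
construction, a trajectory generator that dissociates that dimer through a
programmed bound -> encounter -> unbound schedule, and an overdamped-limit
(BAOAB) Langevin simulator that runs metadynamics on a one-dimensional
collective variable with a known free-energy profile.

The dimer geometry is a regular cylindrical lattice.  Each chain has an
interface ring of residues facing the partner chain across the x = 0 plane
and a rear block of 12-fold rings centred on the x axis.  That symmetry is
deliberate: an interdomain torsion applied to the rear block of chain b
leaves the interface contacts and the exposed surface nearly unchanged, so
the encounter phase perturbs exactly the descriptors it is meant to perturb
(centre-of-mass distance and the designated native contacts) and no others.
One rear residue sits on a wider radius so that the per-domain principal
axes used by the orientation metrics are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc

from ._langevin import run_baoab_metad
from .errors import InvalidParameterError, NumericalError
from .plumed_io import CVSeries, HillsRecord

KB = 0.008314463  # kJ/mol/K

# geometry constants of the toy dimer (Angstrom)
_BACKBONE_X = -3.8          # interface-ring backbone plane of chain a
_CB_FIRM_X = -1.7           # firm contact pseudo side chain (pair distance 3.4)
_CB_MARGINAL_X = -2.22      # marginal contact: 4.44 A, safely inside the cutoff
                            # in the reference but flickering under trajectory jitter
_REAR_X0 = -11.0            # first rear ring plane
_REAR_DX = 6.0              # spacing between rear rings
_REAR_RADIUS = 9.0
_TAIL_RADIUS = 16.0         # one off-ring residue breaks axial symmetry
_RING_SIZE = 12             # rear residues per ring (30 degree spacing)

_ATOM_TEMPLATE = [
    # name, element, offset from the residue base point
    ("N", "N", np.array([0.0, 0.0, 1.0])),
    ("CA", "C", np.array([0.0, 0.0, 0.0])),
    ("C", "C", np.array([0.0, 0.0, -1.0])),
    ("O", "O", np.array([-0.5, 0.0, -1.55])),
]
_ATOMS_PER_RES = 5  # template + CB


@dataclass
class ToyDimer:
    """A mirror-symmetric two-chain pseudo-protein with designed contacts."""

    atoms: struc.AtomArray
    interface_pairs: list[tuple[int, int]]
    marginal_pairs: list[tuple[int, int]]
    residues_per_chain: int
    chains: tuple[str, str] = ("a", "b")
    contact_cutoff: float = 4.5

    @property
    def firm_pairs(self) -> list[tuple[int, int]]:
        return [p for p in self.interface_pairs if p not in self.marginal_pairs]


def build_toy_dimer(
    residues_per_chain: int = 100,
    n_interface_pairs: int = 10,
    seed: int = 0,
    jitter: float = 0.01,
) -> ToyDimer:
    """Construct the two-chain lattice dimer.

    ``n_interface_pairs`` mirror pairs of residues carry a pseudo side chain
    (CB) protruding across the interface so that their minimum inter-chain
    heavy-atom distance is below the 4.5 A contact cutoff; every other
    inter-chain residue pair stays above 5.5 A by construction.  Roughly a
    fifth of the designed pairs are placed marginally (4.3 A) so that the
    fraction of native contacts fluctuates in a noisy bound ensemble, as it
    does in real bound-state trajectories.  A small seeded coordinate jitter
    breaks exact distance ties; the construction is deterministic per seed.
    """
    if residues_per_chain < 4:
        raise InvalidParameterError("residues_per_chain must be >= 4")
    if n_interface_pairs < 1:
        raise InvalidParameterError("n_interface_pairs must be >= 1")
    if n_interface_pairs > residues_per_chain - 3:
        raise InvalidParameterError(
            "need at least 3 rear residues per chain: "
            f"n_interface_pairs <= residues_per_chain - 3 "
            f"({n_interface_pairs} > {residues_per_chain - 3})"
        )
    k = n_interface_pairs
    n_res = residues_per_chain
    n_marginal = k // 5 if k >= 3 else 0

    r_if = max(4.0, 7.0 * k / (2.0 * np.pi))

    base_points = np.empty((n_res, 3))
    cb_x = np.empty(n_res)
    for i in range(k):
        theta = 2.0 * np.pi * i / k
        base_points[i] = (_BACKBONE_X, r_if * np.cos(theta), r_if * np.sin(theta))
        marginal = i >= k - n_marginal
        cb_x[i] = _CB_MARGINAL_X if marginal else _CB_FIRM_X
    n_rear = n_res - k
    for j in range(n_rear):
        ring, pos = divmod(j, _RING_SIZE)
        theta = np.deg2rad(30.0 * pos + 15.0 * (ring % 2))
        radius = _TAIL_RADIUS if j == n_rear - 1 else _REAR_RADIUS
        x = _REAR_X0 - _REAR_DX * ring
        base_points[k + j] = (x, radius * np.cos(theta), radius * np.sin(theta))
        cb_x[k + j] = np.nan  # rear CB points rearward, set below

    coords = []
    chain_ids = []
    res_ids = []
    res_names = []
    atom_names = []
    elements = []
    for chain_id in ("a", "b"):
        for i in range(n_res):
            base = base_points[i]
            for name, element, offset in _ATOM_TEMPLATE:
                coords.append(base + offset)
                chain_ids.append(chain_id)
                res_ids.append(i + 1)
                res_names.append("LEU")
                atom_names.append(name)
                elements.append(element)
            if i < k:
                cb = np.array([cb_x[i], base[1], base[2]])
            else:
                cb = base + np.array([-1.2, 0.0, 0.0])
            coords.append(cb)
            chain_ids.append(chain_id)
            res_ids.append(i + 1)
            res_names.append("LEU")
            atom_names.append("CB")
            elements.append("C")
    coords = np.array(coords)
    # chain b is the mirror image across the interface plane x = 0
    n_chain = n_res * _ATOMS_PER_RES
    coords[n_chain:, 0] *= -1.0

    rng = np.random.default_rng(seed)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)

    atoms = struc.AtomArray(len(coords))
    atoms.coord = coords
    atoms.chain_id = np.array(chain_ids)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(res_names)
    atoms.atom_name = np.array(atom_names)
    atoms.element = np.array(elements)
    atoms.hetero = np.zeros(len(coords), dtype=bool)

    pairs = [(i + 1, i + 1) for i in range(k)]
    marginal = pairs[k - n_marginal :] if n_marginal else []
    return ToyDimer(
        atoms=atoms,
        interface_pairs=pairs,
        marginal_pairs=marginal,
        residues_per_chain=n_res,
    )


@dataclass
class DissociationSchedule:
    """Programmed two-step dissociation: bound -> encounter -> unbound.

    During the encounter window the designated ``released_pairs`` lose their
    interface contact (their chain-b side chain retracts), chain b moves by
    ``encounter_separation`` along ``separation_axis`` and its rear block is
    twisted by ``torsion_deg`` about the interdomain axis.  From ``t_unbound``
    on, chain b is displaced far enough that every inter-chain heavy-atom
    distance exceeds twice the contact cutoff.
    """

    n_frames: int
    t_encounter: int
    t_unbound: int
    separation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    torsion_deg: float = 30.0
    noise_sigma: float = 0.25
    seed: int = 0
    released_pairs: list[tuple[int, int]] | None = None
    encounter_separation: float = 1.0
    unbound_separation: float = 40.0

    def __post_init__(self):
        if not (0 < self.t_encounter < self.t_unbound <= self.n_frames):
            raise InvalidParameterError(
                "require 0 < t_encounter < t_unbound <= n_frames, got "
                f"({self.t_encounter}, {self.t_unbound}, {self.n_frames})"
            )
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        axis = np.asarray(self.separation_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise InvalidParameterError("separation_axis must be non-zero")
        self.separation_axis = tuple(axis / norm)

    def labels(self) -> np.ndarray:
        """Ground-truth per-frame state labels."""
        out = np.array(["bound"] * self.n_frames, dtype=object)
        out[self.t_encounter : self.t_unbound] = "encounter"
        out[self.t_unbound :] = "unbound"
        return out


def _rotation_about_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def generate_dissociation_trajectory(dimer: ToyDimer, schedule: DissociationSchedule):
    """Render the schedule into a multi-frame trajectory of the dimer.

    Returns a :class:`metadiss.descriptors.Trajectory`.  The three phase
    geometries are built once and per-frame Gaussian jitter of width
    ``noise_sigma`` is added on top, so the expected centre-of-mass distance
    is non-decreasing across the phases.
    """
    from .descriptors import Trajectory  # deferred: descriptors is pure analysis

    released = schedule.released_pairs
    if released is None:
        n_rel = max(1, len(dimer.firm_pairs) // 8)
        released = dimer.firm_pairs[:n_rel]
    for pair in released:
        if pair not in dimer.interface_pairs:
            raise InvalidParameterError(f"released pair {pair} is not an interface pair")

    atoms = dimer.atoms
    axis = np.asarray(schedule.separation_axis)
    is_b = atoms.chain_id == "b"
    k = len(dimer.interface_pairs)
    rear_b = is_b & (atoms.res_id > k)

    bound = atoms.coord.copy()

    encounter = bound.copy()
    if schedule.torsion_deg != 0.0:
        rot = _rotation_about_x(schedule.torsion_deg)
        encounter[rear_b] = encounter[rear_b] @ rot.T
    released_b = is_b & np.isin(atoms.res_id, [p[1] for p in released]) & (
        atoms.atom_name == "CB"
    )
    # break the released contacts by sliding their side chain along the
    # interface ring (1.5 ring slots): the atom leaves its partner but stays
    # equally buried in the interface layer, so SASA is barely perturbed
    release_rot = _rotation_about_x(1.5 * 360.0 / max(k, 2))
    encounter[released_b] = encounter[released_b] @ release_rot.T
    encounter[is_b] += schedule.encounter_separation * axis
    # the pairs that are not released persist: their contact side chains hold
    # the bound-pose geometry while the rest of chain b shifts
    persistent = [p for p in dimer.interface_pairs if p not in released]
    persistent_b = is_b & np.isin(atoms.res_id, [p[1] for p in persistent]) & (
        atoms.atom_name == "CB"
    )
    encounter[persistent_b] -= schedule.encounter_separation * axis

    unbound = encounter.copy()
    unbound[is_b] += (schedule.unbound_separation - schedule.encounter_separation) * axis

    rng = np.random.default_rng(schedule.seed)
    frames = np.empty((schedule.n_frames, len(atoms), 3))
    for t in range(schedule.n_frames):
        if t < schedule.t_encounter:
            base = bound
        elif t < schedule.t_unbound:
            base = encounter
        else:
            base = unbound
        if schedule.noise_sigma > 0:
            frames[t] = base + rng.normal(0.0, schedule.noise_sigma, base.shape)
        else:
            frames[t] = base

    stack = struc.AtomArrayStack(schedule.n_frames, len(atoms))
    for category in atoms.get_annotation_categories():
        stack.set_annotation(category, atoms.get_annotation(category))
    stack.coord = frames
    return Trajectory(stack=stack, frame_spacing=1.0)


@dataclass
class PotentialSpec:
    """A 1-D free-energy profile used as ground truth (kJ/mol over nm)."""

    form: str
    domain: tuple[float, float]
    parameters: dict = field(default_factory=dict)
    _table: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def harmonic(cls, k: float, center: float = 0.0, domain=(-2.0, 2.0)):
        """U(s) = k/2 (s - center)^2, k in kJ/mol/nm^2."""
        return cls(form="harmonic", domain=domain, parameters={"k": k, "center": center})

    @classmethod
    def double_well(
        cls,
        positions=(-0.5, 0.5),
        depths=(12.0, 8.0),
        width: float | None = None,
        domain=(-1.5, 1.5),
    ):
        """Two Gaussian wells on a flat baseline.

        Each well has depth ``depths[i]`` below the barrier plateau (the
        baseline is at 0, so the barrier measured from the deeper well equals
        ``max(depths)``).  The default width, a fifth of the well separation,
        keeps the cross-terms at the partner well below 1e-5 of its depth, so
        the nominal depths are exact to well beyond the reconstruction
        tolerances used in the tests.
        """
        if width is None:
            width = abs(positions[1] - positions[0]) / 5.0
        return cls(
            form="double_well",
            domain=domain,
            parameters={
                "positions": tuple(positions),
                "depths": tuple(depths),
                "width": width,
            },
        )

    @classmethod
    def tabulated(cls, x, u, domain=None):
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        if domain is None:
            domain = (float(x[0]), float(x[-1]))
        if x[0] > domain[0] or x[-1] < domain[1]:
            raise InvalidParameterError("tabulated potential must cover the domain")
        spec = cls(form="tabulated", domain=domain)
        spec._table = (x, u)
        return spec

    def energy(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.form == "harmonic":
            p = self.parameters
            return 0.5 * p["k"] * (s - p["center"]) ** 2
        if self.form == "double_well":
            p = self.parameters
            u = np.zeros_like(s)
            for pos, depth in zip(p["positions"], p["depths"]):
                u = u - depth * np.exp(-((s - pos) ** 2) / (2.0 * p["width"] ** 2))
            return u
        if self.form == "tabulated":
            x, u = self._table
            return np.interp(s, x, u)
        raise InvalidParameterError(f"unknown potential form {self.form!r}")


@dataclass
class LangevinParams:
    """Integrator parameters for the 1-D surrogate dynamics."""

    n_steps: int
    temperature: float = 300.0
    friction: float = 1.0   # 1/ps
    timestep: float = 0.002  # ps
    mass: float = 1.0       # reduced units
    seed: int = 0
    x0: float | None = None  # default: minimum of the potential

    def __post_init__(self):
        for name in ("n_steps", "temperature", "friction", "timestep", "mass"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


def simulate_langevin_metadynamics(
    potential: PotentialSpec,
    lv: LangevinParams,
    hill_height: float = 0.1,
    hill_width: float = 0.05,
    deposit_stride: int = 5000,
    save_stride: int = 100,
    grid_points: int = 2001,
) -> tuple[CVSeries, HillsRecord]:
    """Run metadynamics on the potential; return the CV series and the hills.

    Gaussians of the given height (kJ/mol) and width (nm) are deposited at
    the instantaneous CV position every ``deposit_stride`` steps; with
    ``hill_height = 0`` the dynamics is unbiased and the hills record is
    empty.  Reflective walls act at the domain edges.  Identical arguments
    (including the seed) give identical output.
    """
    if hill_height < 0:
        raise InvalidParameterError("hill_height must be >= 0")
    if hill_width <= 0 or deposit_stride <= 0 or save_stride <= 0:
        raise InvalidParameterError("hill_width, deposit_stride, save_stride must be positive")

    grid = np.linspace(potential.domain[0], potential.domain[1], grid_points)
    u = potential.energy(grid)
    if not np.all(np.isfinite(u)):
        bad = grid[~np.isfinite(u)][0]
        raise NumericalError(f"potential is not finite at cv={bad:.6g}")
    f_pot = -np.gradient(u, grid)

    x0 = lv.x0 if lv.x0 is not None else float(grid[np.argmin(u)])
    if not (potential.domain[0] <= x0 <= potential.domain[1]):
        raise InvalidParameterError("x0 outside the potential domain")

    kT = KB * lv.temperature
    t, x, hill_t, hill_c = run_baoab_metad(
        float(x0),
        int(lv.n_steps),
        float(lv.timestep),
        float(lv.mass),
        float(lv.friction),
        float(kT),
        grid,
        f_pot,
        float(hill_height),
        float(hill_width),
        int(deposit_stride),
        int(save_stride),
        int(lv.seed) % (2**32),
    )
    cv = CVSeries(times=t, values=x, name="cv")
    hills = HillsRecord(
        times=hill_t,
        centers=hill_c,
        sigmas=np.full(len(hill_t), hill_width),
        heights=np.full(len(hill_t), hill_height),
        cv_name="cv",
    )
    return cv, hills


def make_system_files(
    out_dir,
    system_id: str,
    well_depth: float,
    n_runs: int = 3,
    seed: int = 0,
    n_frames: int = 100,
    residues_per_chain: int = 60,
    n_interface_pairs: int = 10,
    n_steps: int = 2_000_000,
    deposit_stride: int = 500,
    well_position: float = 0.6,
    domain: tuple[float, float] = (0.2, 2.4),
) -> dict:
    """Write a complete synthetic system to disk: per-run trajectory PDB,
    HILLS and COLVAR files, sharing one toy dimer and one bound-well depth.

    The structural runs are programmed dissociations (transitions at 50%
    and 80% of the frames); the CV runs are Langevin metadynamics on a
    single Gaussian well of the given depth (kJ/mol).  Returns a dict with
    the run paths and the bound CV region, ready to build a system record
    for the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dimer = build_toy_dimer(residues_per_chain, n_interface_pairs, seed=seed)
    potential = PotentialSpec.double_well(
        positions=(well_position, domain[1] - 0.4),
        depths=(well_depth, 0.0),
        domain=domain,
    )
    runs = []
    for r in range(n_runs):
        schedule = DissociationSchedule(
            n_frames=n_frames,
            t_encounter=n_frames // 2,
            t_unbound=int(0.8 * n_frames),
            seed=seed * 1000 + r,
            encounter_separation=0.4,
        )
        traj = generate_dissociation_trajectory(dimer, schedule)
        traj_path = out_dir / f"{system_id}_run{r}.pdb"
        write_trajectory_pdb(traj, traj_path)
        cv, hills = simulate_langevin_metadynamics(
            potential,
            LangevinParams(n_steps=n_steps, seed=seed * 1000 + r),
            hill_height=0.1,
            hill_width=0.05,
            deposit_stride=deposit_stride,
            save_stride=200,
        )
        from .plumed_io import write_colvar, write_hills

        colvar_path = out_dir / f"{system_id}_run{r}.colvar"
        hills_path = out_dir / f"{system_id}_run{r}.hills"
        write_colvar(cv, colvar_path)
        write_hills(hills, hills_path)
        runs.append(
            {
                "trajectory": str(traj_path),
                "hills": str(hills_path),
                "colvar": str(colvar_path),
            }
        )
    return {
        "system_id": system_id,
        "runs": runs,
        "bound_region": (domain[0], well_position + 0.5),
        "true_depth": well_depth,
    }


def write_trajectory_pdb(traj, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(traj.stack)
    pdb.write(str(Path(path)))
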