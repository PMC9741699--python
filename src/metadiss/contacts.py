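"""Typed noncovalent inter-chain contacts, occurrence and coarse-graining.

Contacts between the two chains are detected per frame from explicit
geometric criteria (GetContacts-style defaults, restated here so they are
reproducible): hydrogen bonds subclassified by backbone/side-chain
membership of donor and acceptor, salt bridges, pi-cation, pi-stacking,
aromatic T-stacking and hydrophobic contacts.  Pure distance-based van der
Waals pairs are never emitted.  Per-pair occurrences over a frame window
feed a strict threshold filter and a secondary-structure coarse-graining
for flareplot export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, InvalidParameterError

__all__ = [
    "Contact",
    "ContactCriteria",
    "OccurrenceMatrix",
    "detect_contacts",
    "detect_contacts_trajectory",
    "occurrence",
    "filter_occurrence",
    "coarse_grain",
    "read_ss_annotation",
    "write_occurrence_csv",
    "flareplot_json",
    "CONTACT_TYPES",
]

CONTACT_TYPES = (
    "hbond_bb_bb",
    "hbond_sc_bb",
    "hbond_sc_sc",
    "salt_bridge",
    "pi_cation",
    "pi_stack",
    "t_stack",
    "hydrophobic",
)

# residue-level chemistry tables (standard amino acids; heavy atoms)
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_APOLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
_CATION_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIP": {"ND1", "NE2"},
    "HSP": {"ND1", "NE2"},
}
_ANION_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "HIP": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_SC_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "HIP": {"ND1", "NE2"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
_SC_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"}, "CYS": {"SG"},
}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HIP",
    "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}


@dataclass(frozen=True)
class Contact:
    type: str
    residue_a: tuple[str, int, str]  # (chain, number, name)
    residue_b: tuple[str, int, str]
    frame: int = 0


@dataclass
class ContactCriteria:
    """Geometric thresholds (Angstrom / degrees), all configurable."""

    hbond_dist: float = 3.5
    hbond_angle: float = 110.0  # D-H...A angle, used only when H present
    salt_bridge_dist: float = 4.0
    pi_cation_dist: float = 6.0
    pi_cation_angle: float = 60.0  # cation off ring normal
    pi_stack_dist: float = 7.0
    pi_stack_angle: float = 30.0  # normal-normal
    t_stack_dist_min: float = 5.0
    t_stack_dist_max: float = 7.0
    t_stack_angle_min: float = 60.0
    t_stack_angle_max: float = 90.0
    hydrophobic_dist: float = 4.5


@dataclass
class OccurrenceMatrix:
    """(residue pair, type) -> fraction of window frames with the contact."""

    entries: dict[tuple[tuple, tuple, str], float]
    n_frames: int
    window: str = "all"


class _Residue:
    __slots__ = ("chain", "number", "name", "atoms", "coords")

    def __init__(self, chain, number, name):
        self.chain = chain
        self.number = int(number)
        self.name = name
        self.atoms: list[str] = []
        self.coords: list[np.ndarray] = []

    def key(self):
        return (self.chain, self.number, self.name)

    def get(self, names: Iterable[str]) -> np.ndarray:
        sel = [i for i, a in enumerate(self.atoms) if a in names]
        return np.array([self.coords[i] for i in sel]).reshape(-1, 3)

    def heavy(self, exclude_backbone=False) -> np.ndarray:
        sel = [
            i
            for i, a in enumerate(self.atoms)
            if not a.startswith("H") and not (exclude_backbone and a in _BACKBONE_ATOMS)
        ]
        return np.array([self.coords[i] for i in sel]).reshape(-1, 3)

    def hydrogens_near(self, pos: np.ndarray, max_dist=1.3) -> np.ndarray:
        hs = [c for a, c in zip(self.atoms, self.coords) if a.startswith("H")]
        if not hs:
            return np.empty((0, 3))
        hs = np.array(hs)
        d = np.linalg.norm(hs - pos, axis=1)
        return hs[d <= max_dist]


def _split_residues(frame, chain):
    mask = frame.chain_id == chain
    sub = frame[mask]
    residues = {}
    for i in range(sub.array_length()):
        key = int(sub.res_id[i])
        if key not in residues:
            residues[key] = _Residue(chain, key, sub.res_name[i])
        residues[key].atoms.append(sub.atom_name[i])
        residues[key].coords.append(sub.coord[i])
    return list(residues.values())


def _mindist(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return np.inf
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).min())


def _ring_geometry(res: _Residue):
    names = _RING_ATOMS.get(res.name)
    if names is None:
        return None
    coords = res.get(names)
    if len(coords) < len(names):
        return None
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # ring normal: smallest principal axis
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def _angle_deg(v1, v2) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(abs(c), 0.0, 1.0))))


def _donor_atoms(res: _Residue):
    out = []
    for a, c in zip(res.atoms, res.coords):
        if a == "N":
            out.append((a, c, "bb"))
        elif a in _SC_DONORS.get(res.name, ()):
            out.append((a, c, "sc"))
    return out


def _acceptor_atoms(res: _Residue):
    out = []
    for a, c in zip(res.atoms, res.coords):
        if a in ("O", "OXT"):
            out.append((a, c, "bb"))
        elif a in _SC_ACCEPTORS.get(res.name, ()):
            out.append((a, c, "sc"))
    return out


def _hbonds(ra, rb, crit, ionic_atoms):
    """Directional H-bond check both ways; returns subclassified types."""
    found = set()
    for donor_res, acc_res in ((ra, rb), (rb, ra)):
        for dname, dpos, dkind in _donor_atoms(donor_res):
            for aname, apos, akind in _acceptor_atoms(acc_res):
                if np.linalg.norm(dpos - apos) > crit.hbond_dist:
                    continue
                if (donor_res.key(), dname) in ionic_atoms and (
                    acc_res.key(),
                    aname,
                ) in ionic_atoms:
                    continue  # counted as the salt bridge
                hs = donor_res.hydrogens_near(dpos)
                if len(hs):
                    ok = False
                    for h in hs:
                        v1 = dpos - h
                        v2 = apos - h
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if ang >= crit.hbond_angle:
                            ok = True
                            break
                    if not ok:
                        continue
                kinds = {dkind, akind}
                if kinds == {"bb"}:
                    found.add("hbond_bb_bb")
                elif kinds == {"sc"}:
                    found.add("hbond_sc_sc")
                else:
                    found.add("hbond_sc_bb")
    return found


def detect_contacts(
    frame,
    criteria: Optional[ContactCriteria] = None,
    chain_a: str = "a",
    chain_b: str = "b",
    frame_index: int = 0,
    skipped: Optional[list] = None,
) -> list[Contact]:
    """All typed inter-chain contacts of one frame.

    Nonstandard residues without a typing rule are skipped for the
    chemistry-specific types (collected into ``skipped`` when given) but
    still participate in none; hydrophobic contacts use side-chain carbons
    of apolar residues only.  If hydrogens are absent, hydrogen bonds fall
    back to the distance-only criterion.
    """
    crit = criteria or ContactCriteria()
    res_a = _split_residues(frame, chain_a)
    res_b = _split_residues(frame, chain_b)

    for res in (*res_a, *res_b):
        if res.name not in _STANDARD_RESIDUES and skipped is not None:
            skipped.append(res.key())

    contacts = []
    for ra in res_a:
        ha = ra.heavy()
        for rb in res_b:
            if _mindist(ha, rb.heavy()) > max(
                crit.pi_stack_dist, crit.t_stack_dist_max, crit.pi_cation_dist
            ):
                continue
            pair_types = set()

            # salt bridge: anionic O to cationic N
            ionic_atoms = set()
            for rx, ry in ((ra, rb), (rb, ra)):
                cat = rx.get(_CATION_ATOMS.get(rx.name, set()))
                an = ry.get(_ANION_ATOMS.get(ry.name, set()))
                if cat.size and an.size and _mindist(cat, an) <= crit.salt_bridge_dist:
                    pair_types.add("salt_bridge")
                    for a in _CATION_ATOMS.get(rx.name, ()):
                        ionic_atoms.add((rx.key(), a))
                    for a in _ANION_ATOMS.get(ry.name, ()):
                        ionic_atoms.add((ry.key(), a))

            pair_types |= _hbonds(ra, rb, crit, ionic_atoms)

            # aromatic geometry
            ring_a = _ring_geometry(ra)
            ring_b = _ring_geometry(rb)
            if ring_a and ring_b:
                cen_d = float(np.linalg.norm(ring_a[0] - ring_b[0]))
                nn = _angle_deg(ring_a[1], ring_b[1])
                if cen_d <= crit.pi_stack_dist and nn <= crit.pi_stack_angle:
                    pair_types.add("pi_stack")
                if (
                    crit.t_stack_dist_min <= cen_d <= crit.t_stack_dist_max
                    and crit.t_stack_angle_min <= nn <= crit.t_stack_angle_max
                ):
                    pair_types.add("t_stack")
            for ring_res, cat_res in ((ring_a, rb), (ring_b, ra)):
                if ring_res is None:
                    continue
                cat = cat_res.get(_CATION_ATOMS.get(cat_res.name, set()))
                for c in cat:
                    v = c - ring_res[0]
                    d = float(np.linalg.norm(v))
                    if d <= crit.pi_cation_dist and _angle_deg(v, ring_res[1]) <= crit.pi_cation_angle:
                        pair_types.add("pi_cation")

            # hydrophobic: side-chain carbon pairs of apolar residues
            if ra.name in _APOLAR and rb.name in _APOLAR:
                ca_sc = np.array(
                    [c for a, c in zip(ra.atoms, ra.coords)
                     if a not in _BACKBONE_ATOMS and a.startswith("C")]
                ).reshape(-1, 3)
                cb_sc = np.array(
                    [c for a, c in zip(rb.atoms, rb.coords)
                     if a not in _BACKBONE_ATOMS and a.startswith("C")]
                ).reshape(-1, 3)
                if _mindist(ca_sc, cb_sc) <= crit.hydrophobic_dist:
                    pair_types.add("hydrophobic")

            for t in pair_types:
                contacts.append(
                    Contact(
                        type=t,
                        residue_a=ra.key(),
                        residue_b=rb.key(),
                        frame=frame_index,
                    )
                )
    return contacts


def detect_contacts_trajectory(
    traj,
    criteria: Optional[ContactCriteria] = None,
    chain_a: str = "a",
    chain_b: str = "b",
) -> list[list[Contact]]:
    """Per-frame contact lists for a whole trajectory."""
    return [
        detect_contacts(traj.frame(t), criteria, chain_a, chain_b, frame_index=t)
        for t in range(traj.n_frames)
    ]


def occurrence(
    per_frame_contacts: Sequence[Sequence[Contact]],
    window: Optional[tuple[int, int]] = None,
    label: str = "all",
) -> OccurrenceMatrix:
    """Fraction of window frames in which each (pair, type) occurs."""
    n_total = len(per_frame_contacts)
    start, stop = window if window is not None else (0, n_total)
    start, stop = max(0, start), min(n_total, stop)
    if stop <= start:
        raise InvalidParameterError(f"empty frame window ({start}, {stop})")
    counts: dict = {}
    for frame_contacts in per_frame_contacts[start:stop]:
        seen = set()
        for c in frame_contacts:
            key = (c.residue_a, c.residue_b, c.type)
            if key not in seen:
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
    n = stop - start
    return OccurrenceMatrix(
        entries={k: v / n for k, v in counts.items()}, n_frames=n, window=label
    )


def filter_occurrence(matrix: OccurrenceMatrix, min_occurrence: float) -> OccurrenceMatrix:
    """Keep entries strictly greater than the threshold ("higher than")."""
    if not (0 <= min_occurrence <= 1):
        raise InvalidParameterError("min_occurrence must be in [0, 1]")
    return OccurrenceMatrix(
        entries={k: v for k, v in matrix.entries.items() if v > min_occurrence},
        n_frames=matrix.n_frames,
        window=matrix.window,
    )


def read_ss_annotation(path) -> dict[tuple[str, int], str]:
    """CSV with columns chain, resnum, element -> {(chain, resnum): element}."""
    df = pd.read_csv(path)
    return {
        (str(r.chain), int(r.resnum)): str(r.element) for r in df.itertuples()
    }


def coarse_grain(
    matrix: OccurrenceMatrix,
    ss: dict[tuple[str, int], str],
    aggregation: str = "max",
) -> OccurrenceMatrix:
    """Aggregate residue pairs into secondary-structure element pairs.

    Element labels are chain letter + element letter (e.g. ``a_G``-``b_AB``).
    The default ``max`` aggregation preserves the strongest contact of the
    element pair; ``mean`` and ``sum`` are available.
    """
    if aggregation not in ("max", "mean", "sum"):
        raise InvalidParameterError("aggregation must be max, mean or sum")
    groups: dict = {}
    for (res_a, res_b, ctype), value in matrix.entries.items():
        for res in (res_a, res_b):
            if (res[0], res[1]) not in ss:
                raise AnnotationError(
                    f"residue {res[0]}{res[1]} has no secondary-structure label"
                )
        key = (
            (f"{res_a[0]}_{ss[(res_a[0], res_a[1])]}",),
            (f"{res_b[0]}_{ss[(res_b[0], res_b[1])]}",),
            ctype,
        )
        groups.setdefault(key, []).append(value)
    agg = {"max": max, "sum": sum, "mean": lambda v: sum(v) / len(v)}[aggregation]
    return OccurrenceMatrix(
        entries={k: float(agg(v)) for k, v in groups.items()},
        n_frames=matrix.n_frames,
        window=matrix.window,
    )


def write_occurrence_csv(matrix: OccurrenceMatrix, path) -> None:
    rows = []
    for (res_a, res_b, ctype), value in sorted(matrix.entries.items()):
        if len(res_a) == 3:
            rows.append(
                dict(chain_a=res_a[0], res_a=res_a[1], name_a=res_a[2],
                     chain_b=res_b[0], res_b=res_b[1], name_b=res_b[2],
                     type=ctype, occurrence=value)
            )
        else:  # coarse-grained entries
            rows.append(dict(element_a=res_a[0], element_b=res_b[0],
                             type=ctype, occurrence=value))
    pd.DataFrame(rows).to_csv(path, index=False)


def flareplot_json(
    per_frame_contacts: Sequence[Sequence[Contact]],
    ss: Optional[dict[tuple[str, int], str]] = None,
    path=None,
) -> dict:
    """Flareplot-compatible edge list with per-frame presence."""
    edges: dict = {}
    for t, frame_contacts in enumerate(per_frame_contacts):
        for c in frame_contacts:
            def _name(res):
                base = f"{res[0]}{res[1]}"
                if ss is not None and (res[0], res[1]) in ss:
                    base += ss[(res[0], res[1])]
                return base
            key = (_name(c.residue_a), _name(c.residue_b))
            edges.setdefault(key, set()).add(t)
    out = {
        "edges": [
            {"name1": k[0], "name2": k[1], "frames": sorted(v)}
            for k, v in sorted(edges.items())
        ]
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh)
    return out
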