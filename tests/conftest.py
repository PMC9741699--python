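"""Shared fixtures: every input is generated programmatically at test time."""

import numpy as np
import pytest
import biotite.structure as struc

from metadiss import descriptors as desc_mod
from metadiss import states as states_mod
from metadiss.synthetic import (
    DissociationSchedule,
    LangevinParams,
    PotentialSpec,
    build_toy_dimer,
    generate_dissociation_trajectory,
    simulate_langevin_metadynamics,
)


def make_frame(atoms):
    """Build a biotite AtomArray from (chain, resid, resname, atomname, element, xyz)."""
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a[5] for a in atoms], dtype=float)
    arr.chain_id = np.array([a[0] for a in atoms])
    arr.res_id = np.array([a[1] for a in atoms])
    arr.res_name = np.array([a[2] for a in atoms])
    arr.atom_name = np.array([a[3] for a in atoms])
    arr.element = np.array([a[4] for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    return arr


@pytest.fixture(scope="session")
def dimer():
    return build_toy_dimer(residues_per_chain=60, n_interface_pairs=10, seed=2)


@pytest.fixture(scope="session")
def dimer_native(dimer):
    return desc_mod.define_native_contacts(dimer.atoms, cutoff=dimer.contact_cutoff)


@pytest.fixture(scope="session")
def diss_schedule_1000():
    return DissociationSchedule(
        n_frames=1000, t_encounter=500, t_unbound=800, seed=3,
        encounter_separation=0.4,
    )


@pytest.fixture(scope="session")
def diss_traj_1000(dimer, diss_schedule_1000):
    return generate_dissociation_trajectory(dimer, diss_schedule_1000)


@pytest.fixture(scope="session")
def diss_descriptors_1000(diss_traj_1000, dimer_native):
    return desc_mod.descriptor_timeseries(diss_traj_1000, dimer_native)


@pytest.fixture(scope="session")
def bound_fits_1000(diss_descriptors_1000):
    bound = {k: v.values[:500] for k, v in diss_descriptors_1000.items()}
    return states_mod.fit_state_model(bound)


@pytest.fixture(scope="session")
def double_well():
    """The reference double well: wells at +-0.5 nm, depths 12 and 8 kJ/mol
    below the barrier plateau (depth difference 4, barrier 12)."""
    return PotentialSpec.double_well(
        positions=(-0.5, 0.5), depths=(12.0, 8.0), domain=(-1.5, 1.5)
    )


@pytest.fixture(scope="session")
def double_well_run(double_well):
    """One long metadynamics run with the reference deposition protocol."""
    return simulate_langevin_metadynamics(
        double_well,
        LangevinParams(n_steps=5_000_000, seed=3),
        hill_height=0.1,
        hill_width=0.05,
        deposit_stride=5000,
        save_stride=100,
    )
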