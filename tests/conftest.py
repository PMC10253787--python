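import numpy as np
import pytest

from gatescan import structure_io as sio
from gatescan import synthetic_channel as sc


def make_topology(n_atoms, atom_name="C", element="C", resname="GLY",
                  chain_id="A", residue_numbers=None):
    """A minimal topology for hand-constructed geometries."""
    if residue_numbers is None:
        residue_numbers = np.arange(1, n_atoms + 1)
    return sio.Topology(
        atom_name=[atom_name] * n_atoms,
        element=[element] * n_atoms,
        residue_number=residue_numbers,
        residue_name=[resname] * n_atoms,
        chain_id=[chain_id] * n_atoms,
    )


def make_trajectory(coords, **top_kwargs):
    coords = np.asarray(coords, dtype=float)
    top = make_topology(coords.shape[1], **top_kwargs)
    return sio.Trajectory(top, coords)


@pytest.fixture(scope="session")
def bundle_spec():
    """A compact channel: 4 chains of 24 residues, planted truth everywhere."""
    return sc.ChannelSpec(
        helix_residues=24, residue_start=658, n_frames=200,
        per_residue_sigma=0.3, seed=42,
        gate_aperture=0.9, gate_open_aperture=1.6, open_fraction=0.55,
        n_waters_traversing=2, n_waters_resident=2,
        planted_hbonds=[sc.PlantedHBond(0.75), sc.PlantedHBond(0.30)],
    )


@pytest.fixture(scope="session")
def bundle_dataset(bundle_spec):
    return sc.simulate_trajectory(bundle_spec)


@pytest.fixture(scope="session")
def bundle_traj(bundle_dataset):
    return bundle_dataset[0]


@pytest.fixture(scope="session")
def bundle_manifest(bundle_dataset):
    return bundle_dataset[1]
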