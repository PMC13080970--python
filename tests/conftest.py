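"""Shared fixtures: toy topologies, small planted ensembles, and the
scaled-down activation criteria matching the synthetic scaffold."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrtraj.model import ActivationCriteria, AtomRecord, Frame, Topology, Trajectory
from gpcrtraj.synthetic import SyntheticSpec, generate_ensemble


def make_atom(
    index: int,
    residue_index: int = 1,
    atom_name: str = "CA",
    chain: str = "A",
    charge: float = 0.0,
    sigma: float = 0.3,
    eps: float = 0.0,
    mass: float = 12.0,
    residue_name: str = "ALA",
    element: str = "C",
) -> AtomRecord:
    return AtomRecord(
        atom_index=index,
        atom_name=atom_name,
        element=element,
        residue_index=residue_index,
        residue_name=residue_name,
        chain_id=chain,
        charge=charge,
        lj_sigma=sigma,
        lj_epsilon=eps,
        mass=mass,
    )


def random_two_group_system(
    rng: np.random.Generator,
    n_ligand: int = 30,
    n_receptor: int = 120,
    box_edge: float = 25.0,
    n_residues_per_side: int = 5,
):
    """Random charges/LJ/positions split into ligand and receptor groups,
    several residues per side, inside an orthorhombic box."""
    n = n_ligand + n_receptor
    atoms = []
    for i in range(n):
        if i < n_ligand:
            chain, res = "L", 1 + i % n_residues_per_side
        else:
            chain, res = "A", 1 + (i - n_ligand) % n_residues_per_side
        atoms.append(
            make_atom(
                i,
                residue_index=res,
                chain=chain,
                charge=float(rng.uniform(-1, 1)),
                sigma=float(rng.uniform(0.25, 0.4)),
                eps=float(rng.uniform(0.0, 1.0)),
                mass=float(rng.uniform(1, 20)),
            )
        )
    topology = Topology(
        atoms=atoms,
        groups={
            "ligand": frozenset(range(n_ligand)),
            "receptor": frozenset(range(n_ligand, n)),
        },
    )
    coords = rng.uniform(0, box_edge, size=(n, 3))
    frame = Frame(coords, box=np.array([box_edge] * 3), time=0.0)
    return topology, frame


@pytest.fixture
def toy_criteria() -> ActivationCriteria:
    """Criteria matching the default synthetic scaffold's marker residues."""
    return ActivationCriteria(
        distance_atoms=((10, "CA"), (20, "CA")),
        distance_threshold=19.0,
        angle_atoms=((12, "CA"), (15, "CA"), (5, "CA")),
        angle_threshold=45.0,
    )


@pytest.fixture
def small_ensemble():
    """200-frame planted ensemble with f_active=0.5 and its realized states."""
    spec = SyntheticSpec(n_frames=200, f_active=0.5, seed=42)
    traj, topo, states = generate_ensemble(spec, return_states=True)
    return spec, traj, topo, states


def rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random proper rotation plus translation to an N×3 array."""
    a = rng.standard_normal((3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, 3)
    return coords @ q.T + t
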