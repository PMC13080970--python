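"""Synthetic two-state receptor-like ensembles with planted parameters.

The generator is the package's test bed in place of real MD output: a
Cα scaffold whose activation markers (one distance pair, one angle
triple) are planted on known geometries for the active and inactive
states, a pseudo-ligand pocket with known charges and LJ parameters,
i.i.d. Bernoulli state draws with a planted active-frame fraction, and
isotropic Gaussian positional noise of known amplitude on every atom.
Every downstream stage can therefore be checked against closed-form
expectations: the recovered active fraction against the Bernoulli
fraction, per-residue RMSF against σ√3, pair energies against the
analytic Coulomb/LJ values at the planted distances.

What this emulates — and what it does not: the two-state mixture with
Gaussian noise reproduces the *geometry* of an activation equilibrium
(marker values straddling their thresholds with a margin of at least
5σ) but frames are independent draws, not a correlated MD time series,
and the pseudo-ligand does not move relative to its pocket anchor
except through noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import AtomRecord, Frame, Topology, Trajectory, validate_topology

__all__ = [
    "PocketAtom",
    "PocketResidue",
    "PocketSpec",
    "SyntheticSpec",
    "default_pocket_spec",
    "build_scaffold",
    "generate_ensemble",
    "plant_energy_trajectory",
    "COULOMB_K",
]

# same physical constant the energetics module uses, restated here so the
# analytic fixture values are produced independently of that code path
COULOMB_K = 1389.35458  # kJ/mol · Å / e²

_CA_MASS = 12.011


@dataclass(frozen=True)
class PocketAtom:
    """One pseudo-ligand atom: nonbonded parameters plus its offset (Å)
    from the residue's placement point."""

    name: str
    charge: float
    lj_sigma: float  # nm
    lj_epsilon: float  # kJ/mol
    mass: float
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PocketResidue:
    """A 1–3 atom pseudo-ligand residue anchored to a receptor residue:
    placed ``distance`` Å from that residue's Cα along ``direction``."""

    residue_name: str
    atoms: tuple[PocketAtom, ...]
    anchor_residue: int
    distance: float
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class PocketSpec:
    """Pseudo-ligand layout plus charge/LJ overrides on receptor Cαs.

    ``receptor_params`` maps a receptor residue index to
    (charge e, sigma nm, epsilon kJ/mol) for its Cα; unlisted receptor
    atoms stay neutral with ε = 0 so planted pair energies are exact.
    ``receptor_residue_names`` overrides 3-letter names (default ALA).
    """

    residues: tuple[PocketResidue, ...]
    receptor_params: Mapping[int, tuple[float, float, float]] = field(
        default_factory=dict
    )
    receptor_residue_names: Mapping[int, str] = field(default_factory=dict)


def default_pocket_spec(anchor_residue: int = 1, distance: float = 10.0) -> PocketSpec:
    """One +1e pseudo-ligand atom 10 Å above a −1e pocket Cα: the
    single-pair system whose Coulomb energy is −k/10 = −138.935458
    kJ/mol with a closed-form LJ term."""
    return PocketSpec(
        residues=(
            PocketResidue(
                residue_name="LIG",
                atoms=(PocketAtom("X1", +1.0, 0.30, 0.50, 100.0),),
                anchor_residue=anchor_residue,
                distance=distance,
            ),
        ),
        receptor_params={anchor_residue: (-1.0, 0.30, 0.50)},
    )


@dataclass
class SyntheticSpec:
    """Full parameterization of a planted two-state ensemble.

    ``noise_sigma`` is the per-coordinate isotropic Gaussian amplitude
    in Å — a scalar for all residues or a map residue index → σ (with
    ``noise_sigma_default`` for the rest), which lets tests keep an
    alignment subset rigid.  Marker geometries default to (17 Å, 55°)
    active and (21 Å, 35°) inactive, bracketing the 19 Å / 45°
    classification thresholds with a wide margin.
    """

    n_frames: int = 1000
    f_active: float = 0.5
    noise_sigma: Union[float, Mapping[int, float]] = 0.10
    noise_sigma_default: float = 0.10
    active_marker: tuple[float, float] = (17.0, 55.0)
    inactive_marker: tuple[float, float] = (21.0, 35.0)
    n_residues: int = 30
    distance_residues: tuple[int, int] = (10, 20)
    angle_residues: tuple[int, int, int] = (12, 15, 5)
    ligand_layout: Optional[PocketSpec] = None
    box: Optional[tuple[float, float, float]] = (200.0, 200.0, 200.0)
    seed: int = 0
    dt: float = 1.0  # ps between saved frames
    distance_threshold: float = 19.0
    angle_threshold: float = 45.0

    def sigma_for(self, residue_index: int) -> float:
        if isinstance(self.noise_sigma, Mapping):
            return float(self.noise_sigma.get(residue_index, self.noise_sigma_default))
        return float(self.noise_sigma)

    def max_sigma(self) -> float:
        if isinstance(self.noise_sigma, Mapping):
            vals = list(self.noise_sigma.values()) + [self.noise_sigma_default]
            return float(max(vals))
        return float(self.noise_sigma)

    def validate(self) -> None:
        if not (0.0 <= self.f_active <= 1.0):
            raise ValueError("f_active must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        markers = self.distance_residues + self.angle_residues
        if len(set(markers)) != 5:
            raise ValueError("marker residue indices must be five distinct residues")
        needed = max(markers)
        if self.n_residues < needed:
            raise ValueError(
                f"n_residues ({self.n_residues}) smaller than largest marker "
                f"residue index ({needed})"
            )
        # only noise on the marker residues themselves can flip a frame
        sigma = max(self.sigma_for(r)
                    for r in self.distance_residues + self.angle_residues)
        for d, _ in (self.active_marker, self.inactive_marker):
            if abs(d - self.distance_threshold) <= 5.0 * sigma:
                raise ValueError(
                    "marker distance margin must exceed 5×noise_sigma; "
                    f"|{d} − {self.distance_threshold}| Å vs σ = {sigma} Å"
                )
        # angle jitter scale for 10 Å marker arms: ~σ√2/arm in radians
        ang_sigma = float(np.degrees(sigma * np.sqrt(2.0) / _ARM_LENGTH))
        for _, a in (self.active_marker, self.inactive_marker):
            if abs(a - self.angle_threshold) <= 5.0 * ang_sigma:
                raise ValueError(
                    "marker angle margin must exceed 5× the angle jitter scale"
                )
        sides_d = (
            self.active_marker[0] < self.distance_threshold,
            self.inactive_marker[0] < self.distance_threshold,
        )
        sides_a = (
            self.active_marker[1] > self.angle_threshold,
            self.inactive_marker[1] > self.angle_threshold,
        )
        if sides_d != (True, False) or sides_a != (True, False):
            raise ValueError(
                "active/inactive markers must sit on opposite sides of both thresholds"
            )


_ARM_LENGTH = 10.0  # Å, both arms of the planted marker angle
_ANGLE_CLUSTER_Y = 40.0  # Å, keeps the angle triple clear of the helix


def _scaffold_coordinates(spec: SyntheticSpec, marker: tuple[float, float]) -> np.ndarray:
    """Cα positions for one reference state.

    Non-marker residues sit on a compact helix (12 Å radius, 18
    residues per turn, 1.5 Å rise); the marker distance pair and angle
    triple are placed explicitly so the planted (distance, angle) are
    exact.  Only marker atoms differ between states.
    """
    d_plant, theta_plant = marker
    n = spec.n_residues
    coords = np.empty((n, 3))
    i = np.arange(n)
    phi = 2.0 * np.pi * i / 18.0
    coords[:, 0] = 12.0 * np.cos(phi)
    coords[:, 1] = 12.0 * np.sin(phi)
    coords[:, 2] = 1.5 * i
    r_d1, r_d2 = spec.distance_residues
    r_a1, r_v, r_a2 = spec.angle_residues
    coords[r_d1 - 1] = (0.0, -20.0, 0.0)
    coords[r_d2 - 1] = (d_plant, -20.0, 0.0)
    theta = np.radians(theta_plant)
    coords[r_v - 1] = (0.0, _ANGLE_CLUSTER_Y, 0.0)
    coords[r_a1 - 1] = (_ARM_LENGTH, _ANGLE_CLUSTER_Y, 0.0)
    coords[r_a2 - 1] = (
        _ARM_LENGTH * np.cos(theta),
        _ANGLE_CLUSTER_Y + _ARM_LENGTH * np.sin(theta),
        0.0,
    )
    return coords


def build_scaffold(
    spec: SyntheticSpec,
    ecl2_residues: Optional[Sequence[int]] = None,
) -> tuple[Topology, Frame, Frame]:
    """Topology plus (active, inactive) reference frames.

    The two references differ only in the marker atoms' geometry; the
    pseudo-ligand (``spec.ligand_layout``, defaulting to the single
    ±1e pair of :func:`default_pocket_spec`) is anchored identically in
    both.  ``ecl2_residues`` optionally adds an "ECL2" group over those
    receptor residues' Cαs.
    """
    spec.validate()
    pocket = spec.ligand_layout or default_pocket_spec()
    atoms: list[AtomRecord] = []
    for res in range(1, spec.n_residues + 1):
        charge, sig, eps = pocket.receptor_params.get(res, (0.0, 0.30, 0.0))
        atoms.append(
            AtomRecord(
                atom_index=res - 1,
                atom_name="CA",
                element="C",
                residue_index=res,
                residue_name=pocket.receptor_residue_names.get(res, "ALA"),
                chain_id="A",
                charge=charge,
                lj_sigma=sig,
                lj_epsilon=eps,
                mass=_CA_MASS,
            )
        )
    n_rec = len(atoms)
    lig_positions: list[np.ndarray] = []
    rec_active = _scaffold_coordinates(spec, spec.active_marker)
    rec_inactive = _scaffold_coordinates(spec, spec.inactive_marker)
    next_index = n_rec
    for lig_res_num, pres in enumerate(pocket.residues, start=1):
        direction = np.asarray(pres.direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        base = rec_active[pres.anchor_residue - 1] + pres.distance * direction
        for patom in pres.atoms:
            atoms.append(
                AtomRecord(
                    atom_index=next_index,
                    atom_name=patom.name,
                    element="X",
                    residue_index=lig_res_num,
                    residue_name=pres.residue_name,
                    chain_id="L",
                    charge=patom.charge,
                    lj_sigma=patom.lj_sigma,
                    lj_epsilon=patom.lj_epsilon,
                    mass=patom.mass,
                )
            )
            lig_positions.append(base + np.asarray(patom.offset, dtype=float))
            next_index += 1
    groups: dict[str, frozenset[int]] = {
        "receptor": frozenset(range(n_rec)),
        "ligand": frozenset(range(n_rec, next_index)),
    }
    if ecl2_residues is not None:
        groups["ECL2"] = frozenset(r - 1 for r in ecl2_residues)
    topology = Topology(atoms=atoms, groups=groups)
    violations = validate_topology(topology)
    if violations:  # pragma: no cover - construction bug guard
        raise AssertionError(f"scaffold topology invalid: {violations}")
    lig_arr = np.array(lig_positions) if lig_positions else np.empty((0, 3))
    box = None if spec.box is None else np.asarray(spec.box, dtype=float)
    frame_active = Frame(np.vstack([rec_active, lig_arr]), box=box, time=0.0)
    frame_inactive = Frame(np.vstack([rec_inactive, lig_arr]), box=box, time=0.0)
    return topology, frame_active, frame_inactive


def generate_ensemble(
    spec: SyntheticSpec, return_states: bool = False
) -> Union[tuple[Trajectory, Topology], tuple[Trajectory, Topology, np.ndarray]]:
    """Draw the planted ensemble.

    Frame t takes the active reference with probability ``f_active``
    (i.i.d. Bernoulli) and adds i.i.d. isotropic Gaussian noise with
    the residue's σ to every atom.  Deterministic under ``spec.seed``;
    frame times are evenly spaced at ``spec.dt`` ps.  With
    ``return_states`` the realized per-frame Bernoulli states (True =
    active reference) are returned as well, so recovery tests can
    compare against the exact planted series rather than its
    expectation.
    """
    spec.validate()
    topology, ref_active, ref_inactive = build_scaffold(spec)
    rng = np.random.default_rng(spec.seed)
    states = rng.random(spec.n_frames) < spec.f_active
    sigma_per_atom = np.array(
        [spec.sigma_for(a.residue_index) if a.chain_id == "A" else spec.sigma_for(-1)
         for a in topology.atoms]
    )
    # ligand atoms (chain L) use the default sigma unless mapped under -1
    noise = rng.standard_normal((spec.n_frames, topology.n_atoms, 3))
    noise *= sigma_per_atom[None, :, None]
    box = None if spec.box is None else np.asarray(spec.box, dtype=float)
    frames = []
    for t in range(spec.n_frames):
        base = ref_active.coordinates if states[t] else ref_inactive.coordinates
        frames.append(Frame(base + noise[t], box=box, time=t * spec.dt))
    trajectory = Trajectory(frames=frames)
    if return_states:
        return trajectory, topology, states
    return trajectory, topology


def plant_energy_trajectory(
    pair_distance_series: Sequence[float],
    q_i: float = 1.0,
    q_j: float = -1.0,
    lj_params: tuple[float, float, float, float] = (0.30, 0.30, 0.50, 0.50),
    box: Optional[tuple[float, float, float]] = None,
    cutoff: float = 10.0,
    dt: float = 1.0,
) -> tuple[Trajectory, Topology, list[tuple[float, float]]]:
    """Two-atom system with exact closed-form per-frame energies.

    Atom 0 ("ligand", charge ``q_i``) stays at the origin; atom 1
    ("receptor", charge ``q_j``) sits at (d, 0, 0) for each planted
    distance d (Å).  ``lj_params`` is (σ_i nm, σ_j nm, ε_i, ε_j).
    Returns the trajectory, its topology, and the analytic
    (Coulomb, LJ) series with plain truncation at ``cutoff`` —
    computed here from the formulas directly, as an independent fixture
    for the energetics stage.
    """
    sig_i, sig_j, eps_i, eps_j = lj_params
    if any(d <= 0 for d in pair_distance_series):
        raise ValueError("planted distances must be positive")
    atoms = [
        AtomRecord(0, "X1", "X", 1, "LIG", "L", q_i, sig_i, eps_i, 100.0),
        AtomRecord(1, "X2", "X", 1, "REC", "A", q_j, sig_j, eps_j, 100.0),
    ]
    topology = Topology(
        atoms=atoms,
        groups={"ligand": frozenset({0}), "receptor": frozenset({1})},
    )
    box_arr = None if box is None else np.asarray(box, dtype=float)
    frames = []
    analytic: list[tuple[float, float]] = []
    sigma_ij = 0.5 * (sig_i + sig_j) * 10.0  # nm -> Å
    eps_ij = float(np.sqrt(eps_i * eps_j))
    for t, d in enumerate(pair_distance_series):
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        frames.append(Frame(coords, box=box_arr, time=t * dt))
        if d > cutoff:
            analytic.append((0.0, 0.0))
        else:
            coul = COULOMB_K * q_i * q_j / d
            sr6 = (sigma_ij / d) ** 6
            analytic.append((coul, 4.0 * eps_ij * (sr6 * sr6 - sr6)))
    return Trajectory(frames=frames), topology, analytic
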