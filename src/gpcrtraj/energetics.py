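"""Pairwise nonbonded ligand–receptor interaction energies.

Implements the short-range, plainly-truncated Coulomb + Lennard-Jones
cross-group sum and its exact per-residue decomposition.  For a pair at
minimum-image distance r (Å) within the cutoff:

    E_coul = k q_i q_j / r,          k = 1389.35458 kJ/mol·Å·e⁻²
    E_lj   = 4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶]

with Lorentz–Berthelot combination (σ arithmetic, ε geometric mean;
Amber-family convention).  No long-range (Ewald/PME) correction is
applied: only the pairwise short-range part admits a well-defined
per-group and per-residue decomposition, so absolute totals are not
comparable to mesh-Ewald engine output, while decompositions and
between-ligand comparisons are.  Ligand and receptor are distinct
molecules, so no cross-group bonded exclusions or 1–4 scaling exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import EnergyBreakdown, Frame, Topology, Trajectory
from .geometry import min_image_displacement

__all__ = [
    "COULOMB_CONSTANT_KJ_MOL_A",
    "NonbondedConfig",
    "pair_energy",
    "group_interaction_energy",
    "residue_decomposition",
    "trajectory_energy_series",
]

#: Coulomb prefactor in kJ·mol⁻¹·Å·e⁻² (= 138.935458 kJ·mol⁻¹·nm·e⁻²),
#: i.e. N_A e² / (4π ε₀) expressed per Ångström.
COULOMB_CONSTANT_KJ_MOL_A = 1389.35458

_NM_TO_A = 10.0


@dataclass(frozen=True)
class NonbondedConfig:
    """Cutoff (Å), Coulomb prefactor, combination rule, truncation.

    Only plain (unshifted) truncation and Lorentz–Berthelot combination
    are supported; the fields exist so reports can state the convention.
    """

    cutoff: float = 10.0
    coulomb_constant: float = COULOMB_CONSTANT_KJ_MOL_A
    combination_rule: str = "Lorentz-Berthelot"
    truncation: str = "plain"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.combination_rule != "Lorentz-Berthelot":
            raise ValueError("only Lorentz-Berthelot combination is supported")
        if self.truncation != "plain":
            raise ValueError("only plain truncation is supported")


def pair_energy(
    q_i: float,
    q_j: float,
    sigma_i: float,
    sigma_j: float,
    eps_i: float,
    eps_j: float,
    r: float,
    config: NonbondedConfig = NonbondedConfig(),
) -> tuple[float, float]:
    """(Coulomb, LJ) energy in kJ/mol of one atom pair at distance r (Å).

    ``sigma_*`` in nm, ``eps_*`` in kJ/mol.  Both terms are exactly zero
    beyond the cutoff; r = 0 raises a singularity error.
    """
    if r == 0.0:
        raise ZeroDivisionError("pair distance is zero (overlapping atoms)")
    if r < 0:
        raise ValueError("distance must be non-negative")
    if r > config.cutoff:
        return (0.0, 0.0)
    coul = config.coulomb_constant * q_i * q_j / r
    eps_ij = np.sqrt(eps_i * eps_j)
    if eps_ij == 0.0:
        lj = 0.0
    else:
        sigma_ij = 0.5 * (sigma_i + sigma_j) * _NM_TO_A
        sr6 = (sigma_ij / r) ** 6
        lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    return (float(coul), float(lj))


def _pair_matrices(
    frame: Frame,
    topology: Topology,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    config: NonbondedConfig,
    box: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Coulomb and LJ energy matrices (|a| × |b|) for all cross pairs,
    already truncated at the cutoff."""
    if box is None:
        box = frame.box
    pos_a = frame.coordinates[idx_a]
    pos_b = frame.coordinates[idx_b]
    disp = min_image_displacement(pos_a[:, None, :], pos_b[None, :, :], box)
    r = np.sqrt((disp ** 2).sum(axis=2))
    if np.any(r == 0.0):
        raise ZeroDivisionError("overlapping atoms across groups (r = 0)")
    within = r <= config.cutoff
    q = topology.charges()
    sig = topology.lj_sigmas_nm() * _NM_TO_A
    eps = topology.lj_epsilons()
    coul = config.coulomb_constant * np.outer(q[idx_a], q[idx_b]) / r
    eps_ij = np.sqrt(np.outer(eps[idx_a], eps[idx_b]))
    sig_ij = 0.5 * (sig[idx_a][:, None] + sig[idx_b][None, :])
    sr6 = (sig_ij / r) ** 6
    lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    coul[~within] = 0.0
    lj[~within] = 0.0
    return coul, lj


def group_interaction_energy(
    frame: Frame,
    topology: Topology,
    group_a: str = "ligand",
    group_b: str = "receptor",
    config: NonbondedConfig = NonbondedConfig(),
    box: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Total (Coulomb, LJ) cross-group interaction energy of one frame.

    Sum of ``pair_energy`` over every inter-group pair at its
    minimum-image distance.  Symmetric in the two groups, which must be
    disjoint.
    """
    a = topology.group(group_a)
    b = topology.group(group_b)
    if a & b:
        raise ValueError(f"groups {group_a!r} and {group_b!r} overlap")
    if not a or not b:
        return (0.0, 0.0)
    idx_a = np.fromiter(sorted(a), dtype=int)
    idx_b = np.fromiter(sorted(b), dtype=int)
    coul, lj = _pair_matrices(frame, topology, idx_a, idx_b, config, box)
    return (float(coul.sum()), float(lj.sum()))


def residue_decomposition(
    frame: Frame,
    topology: Topology,
    side: str = "receptor",
    config: NonbondedConfig = NonbondedConfig(),
    box: Optional[np.ndarray] = None,
    group_a: str = "ligand",
    group_b: str = "receptor",
) -> dict[tuple[str, int], tuple[float, float]]:
    """Per-residue (Coulomb, LJ) contributions on one side of the
    cross-group sum.

    The values over all residues of either side sum exactly to
    ``group_interaction_energy`` — the identical pair list is binned,
    never recomputed.
    """
    if side not in (group_a, group_b):
        raise ValueError(f"side must be {group_a!r} or {group_b!r}")
    a = topology.group(group_a)
    b = topology.group(group_b)
    if a & b:
        raise ValueError(f"groups {group_a!r} and {group_b!r} overlap")
    idx_a = np.fromiter(sorted(a), dtype=int)
    idx_b = np.fromiter(sorted(b), dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        return {}
    coul, lj = _pair_matrices(frame, topology, idx_a, idx_b, config, box)
    side_idx, axis = (idx_a, 1) if side == group_a else (idx_b, 0)
    coul_per_atom = coul.sum(axis=axis)
    lj_per_atom = lj.sum(axis=axis)
    out: dict[tuple[str, int], tuple[float, float]] = {}
    for rid in topology.residues_of(side):
        out[rid] = (0.0, 0.0)
    for atom_idx, c, l in zip(side_idx, coul_per_atom, lj_per_atom):
        rid = topology.atoms[int(atom_idx)].residue_id()
        prev = out.get(rid, (0.0, 0.0))
        out[rid] = (prev[0] + float(c), prev[1] + float(l))
    return out


def trajectory_energy_series(
    trajectory: Trajectory,
    topology: Topology,
    config: NonbondedConfig = NonbondedConfig(),
    stride: int = 1,
    side: str = "receptor",
    box: Optional[np.ndarray] = None,
) -> EnergyBreakdown:
    """Interaction-energy statistics over the retained frames.

    Returns the per-frame (time, Coulomb, LJ) series, means and
    per-frame standard deviations of Coulomb/LJ/total, and per-residue
    means for the chosen decomposition side, all over the same frame
    set (discard window honored, deterministic stride subsampling).
    """
    frames = trajectory.retained(stride)
    per_frame: list[tuple[float, float, float]] = []
    residue_sums: dict[tuple[str, int], np.ndarray] = {}
    for fr in frames:
        dec = residue_decomposition(fr, topology, side=side, config=config, box=box)
        c_tot = sum(v[0] for v in dec.values())
        l_tot = sum(v[1] for v in dec.values())
        per_frame.append((fr.time, float(c_tot), float(l_tot)))
        for rid, (c, l) in dec.items():
            acc = residue_sums.setdefault(rid, np.zeros(2))
            acc += (c, l)
    arr = np.array([(c, l) for _, c, l in per_frame], dtype=float)
    totals = arr.sum(axis=1)
    n = len(frames)
    per_residue = {
        rid: (float(v[0] / n), float(v[1] / n)) for rid, v in residue_sums.items()
    }
    return EnergyBreakdown(
        coulomb_mean=float(arr[:, 0].mean()),
        lj_mean=float(arr[:, 1].mean()),
        total_mean=float(totals.mean()),
        coulomb_sd=float(arr[:, 0].std()),
        lj_sd=float(arr[:, 1].std()),
        total_sd=float(totals.std()),
        per_frame=per_frame,
        per_residue=per_residue,
        decomposition_side=side,
    )
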