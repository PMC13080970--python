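"""Binding-pocket contact census and center-of-mass penetration metrics.

A receptor residue is *in contact* with the ligand in a frame when its
minimum atom–atom minimum-image distance to any ligand atom is within
the cutoff (default 3.0 Å, inclusive).  Residues whose contact
occupancy over the retained frames reaches a threshold (default 0.5)
form the census and are typed by side-chain chemistry.

The default side-chain class table places tyrosine and proline with
the hydrophobics and histidine with the charged residues; glycine is
grouped with the polar-uncharged set.  These placements are
conventions, and the table is fully overridable.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .model import ContactCensus, Frame, Topology, Trajectory
from .geometry import center_of_mass, min_image_displacement

__all__ = [
    "DEFAULT_CLASS_TABLE",
    "classify_residue",
    "contact_census",
    "com_distance_series",
    "penetration_report",
]

DEFAULT_CLASS_TABLE: dict[str, str] = {
    **{r: "hydrophobic" for r in
       ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR")},
    **{r: "charged" for r in ("ASP", "GLU", "LYS", "ARG", "HIS")},
    **{r: "polar_uncharged" for r in
       ("SER", "THR", "ASN", "GLN", "CYS", "GLY")},
}

CLASS_NAMES = ("hydrophobic", "charged", "polar_uncharged", "other")


def classify_residue(
    residue_name: str, class_table: Optional[Mapping[str, str]] = None
) -> str:
    """Side-chain class of a 3-letter residue code; unknown codes are
    ``"other"``."""
    table = DEFAULT_CLASS_TABLE if class_table is None else class_table
    return table.get(residue_name.upper(), "other")


def contact_census(
    trajectory: Trajectory,
    topology: Topology,
    cutoff: float = 3.0,
    class_table: Optional[Mapping[str, str]] = None,
    box: Optional[np.ndarray] = None,
    occupancy_threshold: float = 0.5,
    stride: int = 1,
    heavy_atoms_only: bool = False,
) -> ContactCensus:
    """Census of receptor residues contacting the ligand.

    Returns per-residue occupancies, the mean per-frame contact count,
    and side-chain class counts over residues with occupancy at or
    above ``occupancy_threshold``.  ``heavy_atoms_only`` drops
    hydrogens from the distance test on both sides.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = sorted(topology.group("ligand"))
    rec = sorted(topology.group("receptor"))
    if not lig:
        raise ValueError("empty ligand group")
    if heavy_atoms_only:
        lig = [i for i in lig if topology.atoms[i].element.upper() != "H"]
        rec = [i for i in rec if topology.atoms[i].element.upper() != "H"]
        if not lig:
            raise ValueError("empty ligand group after dropping hydrogens")
    lig_idx = np.asarray(lig, dtype=int)
    rec_idx = np.asarray(rec, dtype=int)
    rec_residues = topology.residues_of("receptor")
    rid_order = {rid: k for k, rid in enumerate(rec_residues)}
    rec_res_codes = np.array(
        [rid_order[topology.atoms[i].residue_id()] for i in rec_idx], dtype=int
    )
    frames = trajectory.retained(stride)
    hits = np.zeros(len(rec_residues), dtype=int)
    count_sum = 0
    for fr in frames:
        b = fr.box if box is None else box
        disp = min_image_displacement(
            fr.coordinates[rec_idx][:, None, :], fr.coordinates[lig_idx][None, :, :], b
        )
        min_r2 = (disp ** 2).sum(axis=2).min(axis=1)
        atom_contact = min_r2 <= cutoff * cutoff
        res_contact = np.zeros(len(rec_residues), dtype=bool)
        np.logical_or.at(res_contact, rec_res_codes, atom_contact)
        hits += res_contact
        count_sum += int(res_contact.sum())
    occ = hits / len(frames)
    per_residue = {rid: float(occ[k]) for rid, k in rid_order.items()}
    contacting = [
        rid for rid in rec_residues if per_residue[rid] >= occupancy_threshold
    ]
    class_counts = {c: 0 for c in CLASS_NAMES}
    for rid in contacting:
        cls = classify_residue(topology.residue_name_of(rid), class_table)
        class_counts[cls] = class_counts.get(cls, 0) + 1
    return ContactCensus(
        per_residue_occupancy=per_residue,
        mean_contact_count=count_sum / len(frames),
        class_counts=class_counts,
        contacting_residues=contacting,
    )


def com_distance_series(
    trajectory: Trajectory,
    topology: Topology,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    box: Optional[np.ndarray] = None,
    stride: int = 1,
) -> tuple[list[float], float]:
    """Per-frame mass-weighted COM distance (Å) between two residues,
    under minimum image, plus its mean over retained frames."""
    atoms_a = topology.residue_atoms(residue_a)
    atoms_b = topology.residue_atoms(residue_b)
    series: list[float] = []
    for fr in trajectory.retained(stride):
        b = fr.box if box is None else box
        com_a = center_of_mass(fr, atoms_a, topology, b)
        com_b = center_of_mass(fr, atoms_b, topology, b)
        series.append(float(np.linalg.norm(min_image_displacement(com_a, com_b, b))))
    return series, float(np.mean(series))


def penetration_report(
    series_a: Mapping[str, tuple[Sequence[float], float]],
    series_b: Mapping[str, tuple[Sequence[float], float]],
) -> dict[str, float]:
    """Per-pair change in mean COM distance between two systems.

    Both maps go from a pair label to ``(series, mean)`` as returned by
    :func:`com_distance_series`.  The sign convention is
    Δ = mean(system B) − mean(system A): positive Δ means the pair sits
    farther apart in system B (shallower ligand penetration there).
    """
    missing = set(series_a) ^ set(series_b)
    if missing:
        raise KeyError(f"residue pairs not present in both systems: {sorted(missing)}")
    return {
        label: float(series_b[label][1] - series_a[label][1]) for label in series_a
    }
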