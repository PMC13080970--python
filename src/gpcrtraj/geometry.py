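"""PBC-aware geometric primitives: minimum image, distances, angles,
mass-weighted centers, Kabsch superposition and RMSF.

Only orthorhombic boxes are supported; a triclinic request raises.  All
lengths are Å, angles degrees.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import Frame, RmsfResult, Topology, Trajectory

__all__ = [
    "min_image_displacement",
    "distance",
    "angle",
    "center_of_mass",
    "kabsch_superpose",
    "rmsf",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Zero-length arm, collinear reference set, or similar degeneracy."""


def min_image_displacement(
    a: np.ndarray, b: np.ndarray, box: Optional[np.ndarray] = None
) -> np.ndarray:
    """Displacement ``b - a`` under the orthorhombic minimum-image
    convention; plain difference when ``box`` is None.

    Broadcasts over leading axes, so ``a`` and ``b`` may be stacks of
    positions.  Each returned component has magnitude ≤ box/2.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return d


def distance(
    frame: Frame, atom_i: int, atom_j: int, box: Optional[np.ndarray] = None
) -> float:
    """Minimum-image distance (Å) between two atoms of a frame."""
    if box is None:
        box = frame.box
    d = min_image_displacement(frame.coordinates[atom_i], frame.coordinates[atom_j], box)
    return float(np.linalg.norm(d))


def angle(
    frame: Frame,
    atom_a: int,
    atom_vertex: int,
    atom_c: int,
    box: Optional[np.ndarray] = None,
) -> float:
    """Angle (degrees, in [0, 180]) at ``atom_vertex`` between the arms
    to ``atom_a`` and ``atom_c``, each arm taken under minimum image."""
    if box is None:
        box = frame.box
    v = frame.coordinates[atom_vertex]
    u1 = min_image_displacement(v, frame.coordinates[atom_a], box)
    u2 = min_image_displacement(v, frame.coordinates[atom_c], box)
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("angle arm has zero length")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def center_of_mass(
    frame: Frame,
    atom_set: Sequence[int],
    topology: Topology,
    box: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mass-weighted center (Å) of a set of atoms.

    Under PBC the set is first unwrapped to the image nearest the first
    atom, so a residue straddling a box boundary gets a physically
    sensible center rather than one in the middle of the box.
    """
    idx = list(atom_set)
    if not idx:
        raise ValueError("atom_set must be non-empty")
    if box is None:
        box = frame.box
    pos = frame.coordinates[idx]
    if box is not None:
        ref = pos[0]
        pos = ref + min_image_displacement(ref, pos, box)
    masses = topology.masses()[idx]
    return np.asarray(np.average(pos, axis=0, weights=masses), dtype=float)


def _kabsch_rotations(mobile: np.ndarray, reference: np.ndarray,
                      weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Batched proper rotations aligning centered mobile onto centered
    reference.  ``mobile``/``reference``: (..., M, 3), already centered."""
    if weights is None:
        h = np.swapaxes(mobile, -1, -2) @ reference
    else:
        h = np.swapaxes(mobile * weights[..., None], -1, -2) @ reference
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    # flip the smallest singular direction to enforce det(R) = +1
    flip = np.ones(h.shape[:-2] + (3,))
    flip[..., -1] = np.where(det < 0, -1.0, 1.0)
    # R maps mobile onto reference as x -> R x (rows: x @ R.T)
    r = (np.swapaxes(vt, -1, -2) * flip[..., None, :]) @ np.swapaxes(u, -1, -2)
    return r


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD
    to ``reference``.  The rotation is proper (det +1).  Requires at
    least three non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching M×3 arrays")
    m = mobile.shape[0]
    if m < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be M non-negative values, not all zero")
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(axis=0) / wsum
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    mob0 = mobile - mc
    ref0 = reference - rc
    # rank of the weighted reference cloud: collinear sets cannot pin a rotation
    if np.linalg.matrix_rank(ref0 * np.sqrt(w)[:, None], tol=1e-9) < 2:
        raise DegenerateGeometryError("reference points are collinear or coincident")
    rot = _kabsch_rotations(mob0, ref0, w)
    translation = rc - rot @ mc
    fitted = mob0 @ rot.T
    rmsd = float(np.sqrt((w * ((fitted - ref0) ** 2).sum(axis=1)).sum() / wsum))
    return rot, translation, rmsd


def _align_stack(coords: np.ndarray, reference: np.ndarray,
                 align_idx: np.ndarray) -> np.ndarray:
    """Least-RMSD align every frame of ``coords`` (T, N, 3) onto
    ``reference`` (N, 3) using the alignment subset, then apply the
    transform to all atoms."""
    ref_sub = reference[align_idx]
    ref_c = ref_sub.mean(axis=0)
    mob_sub = coords[:, align_idx, :]
    mob_c = mob_sub.mean(axis=1)
    rots = _kabsch_rotations(mob_sub - mob_c[:, None, :], ref_sub - ref_c)
    out = np.einsum("tij,tnj->tni", rots, coords - mob_c[:, None, :]) + ref_c
    return out


def rmsf(
    trajectory: Trajectory,
    topology: Topology,
    selection: Sequence[int],
    align_selection: Sequence[int],
    stride: int = 1,
) -> RmsfResult:
    """Per-residue Cα root-mean-square fluctuation over a selection.

    Every retained frame is rigid-body aligned on ``align_selection``
    before fluctuations are measured, in two passes: align to the first
    frame, average, then re-align the original frames to that mean and
    recompute the mean.  RMSF_i = sqrt(⟨|x_i − ⟨x_i⟩|²⟩) per selected
    atom; the per-residue value is the RMSF of that residue's selected
    atom and ``selection_sum`` is the sum over the selection.
    """
    sel = np.asarray(list(selection), dtype=int)
    align_idx = np.asarray(list(align_selection), dtype=int)
    if sel.size == 0:
        raise ValueError("selection resolves to no atoms")
    if align_idx.size < 3:
        raise DegenerateGeometryError("alignment selection needs >= 3 atoms")
    frames = trajectory.retained(stride)
    if len(frames) < 2:
        raise ValueError("RMSF needs at least 2 retained frames")
    coords = np.stack([f.coordinates for f in frames])
    # make each frame contiguous: unwrap every atom to the image nearest
    # the frame's first atom, so image jumps never enter the alignment or
    # the fluctuations (assumes the structure fits within half a box)
    for k, fr in enumerate(frames):
        if fr.box is not None:
            anchor = coords[k, 0]
            coords[k] = anchor + min_image_displacement(anchor, coords[k], fr.box)
    aligned = _align_stack(coords, coords[0], align_idx)
    mean1 = aligned.mean(axis=0)
    aligned = _align_stack(coords, mean1, align_idx)
    mean2 = aligned.mean(axis=0)
    fluct = aligned[:, sel, :] - mean2[sel]
    per_atom = np.sqrt((fluct ** 2).sum(axis=2).mean(axis=0))
    per_residue: dict[tuple[str, int], float] = {}
    for atom_idx, value in zip(sel, per_atom):
        rid = topology.atoms[int(atom_idx)].residue_id()
        per_residue[rid] = per_residue.get(rid, 0.0) + float(value)
    return RmsfResult(
        per_residue_rmsf=per_residue,
        selection_sum=float(per_atom.sum()),
    )
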