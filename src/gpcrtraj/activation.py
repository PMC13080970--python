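"""Per-frame GPCR activation-state classification.

A frame is called *active* when the TM5–TM7 marker Cα distance falls
strictly below its threshold and the TM6 marker Cα angle rises
strictly above its threshold (both markers by default; the combination
rule is part of :class:`~gpcrtraj.model.ActivationCriteria`).  Boundary
frames are inactive.  The statistic of interest is the active fraction
of retained frames, optionally pooled over replicate trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import ActivationCriteria, Frame, Topology, Trajectory, resolve_atom
from .geometry import angle as _angle
from .geometry import distance as _distance

__all__ = [
    "FrameClassification",
    "PooledFraction",
    "classify_frame",
    "active_fraction",
    "pooled_fraction",
]


@dataclass(frozen=True)
class FrameClassification:
    active: bool
    distance: float
    angle: float


@dataclass(frozen=True)
class PooledFraction:
    """Replicate-pooled active fraction.

    ``pooled`` is the frame-weighted fraction (total active frames over
    total frames); ``unweighted_mean`` and ``range`` expose the
    per-replicate spread.
    """

    pooled: float
    unweighted_mean: float
    range: tuple[float, float]


def _resolve_criteria(
    topology: Topology, criteria: ActivationCriteria
) -> tuple[tuple[int, int], tuple[int, int, int]]:
    d = tuple(
        resolve_atom(topology, res, name, criteria.chain)
        for res, name in criteria.distance_atoms
    )
    a = tuple(
        resolve_atom(topology, res, name, criteria.chain)
        for res, name in criteria.angle_atoms
    )
    return d, a  # type: ignore[return-value]


def classify_frame(
    frame: Frame,
    topology: Topology,
    criteria: ActivationCriteria,
    box: Optional[np.ndarray] = None,
) -> FrameClassification:
    """Classify one frame and return the measured marker values.

    Active iff distance < threshold AND angle > threshold (strict
    inequalities; "or" combination if configured so on the criteria).
    """
    (i, j), (a, v, c) = _resolve_criteria(topology, criteria)
    d_val = _distance(frame, i, j, box)
    ang_val = _angle(frame, a, v, c, box)
    d_ok = d_val < criteria.distance_threshold
    a_ok = ang_val > criteria.angle_threshold
    active = (d_ok and a_ok) if criteria.combine == "and" else (d_ok or a_ok)
    return FrameClassification(active=active, distance=d_val, angle=ang_val)


def active_fraction(
    trajectory: Trajectory,
    topology: Topology,
    criteria: ActivationCriteria,
    box: Optional[np.ndarray] = None,
    stride: int = 1,
) -> tuple[float, list[bool]]:
    """Fraction of retained frames classified active, with the
    per-frame boolean series for audit."""
    frames = trajectory.retained(stride)
    series = [
        classify_frame(fr, topology, criteria, box).active for fr in frames
    ]
    return (sum(series) / len(series), series)


def pooled_fraction(
    replicate_fractions: Sequence[float],
    replicate_frame_counts: Sequence[int],
) -> PooledFraction:
    """Pool per-replicate active fractions, frame-weighted.

    Equivalent to counting active frames over all replicates at once.
    """
    fr = np.asarray(replicate_fractions, dtype=float)
    counts = np.asarray(replicate_frame_counts, dtype=float)
    if fr.shape != counts.shape or fr.ndim != 1 or fr.size == 0:
        raise ValueError("need equal-length, non-empty fraction and count lists")
    if np.any(counts <= 0):
        raise ValueError("frame counts must be positive")
    pooled = float((fr * counts).sum() / counts.sum())
    return PooledFraction(
        pooled=pooled,
        unweighted_mean=float(fr.mean()),
        range=(float(fr.min()), float(fr.max())),
    )
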