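"""Domain types shared by every analysis stage.

Unit conventions (stated once, used everywhere):

* coordinates, boxes, distances, RMSF — Ångström (PDB convention);
* Lennard-Jones ``sigma`` — nanometre (force-field convention); the
  energetics module converts at its boundary;
* ``epsilon`` and all energies — kJ/mol;
* charges — elementary-charge units; masses — amu; times — picoseconds.

Residue identity is the pair ``(chain_id, residue_index)`` with author
numbering preserved from the source structure; marker residue numbers
(e.g. 218/306 for the SSTR2 TM5–TM7 distance) are configuration values
carried by :class:`ActivationCriteria`, never hard-coded.  Atom indices
are 0-based internally and 1-based in user-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "ActivationCriteria",
    "EnergyBreakdown",
    "ContactCensus",
    "RmsfResult",
    "AtomNotFoundError",
    "AmbiguousSelectionError",
    "validate_topology",
    "resolve_atom",
]


class AtomNotFoundError(KeyError):
    """Raised when a (residue, atom-name) selection matches no atom."""


class AmbiguousSelectionError(KeyError):
    """Raised when a selection matches more than one atom and no chain
    was given to disambiguate."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its identity and nonbonded parameters.

    ``charge`` in e, ``lj_sigma`` in nm, ``lj_epsilon`` in kJ/mol,
    ``mass`` in amu.  ``residue_index`` uses author numbering.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    charge: float
    lj_sigma: float
    lj_epsilon: float
    mass: float

    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class Topology:
    """Ordered atom list plus named group selections.

    ``groups`` maps a group name to a set of 0-based atom indices.  The
    groups ``"ligand"`` and ``"receptor"`` must exist and be disjoint
    for the analyses in this package; waters/ions/lipids present in a
    trajectory but in neither group are simply ignored.
    """

    atoms: list[AtomRecord]
    groups: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self.groups = {k: frozenset(v) for k, v in self.groups.items()}
        self._by_residue: dict[tuple[str, int], list[int]] = {}
        for a in self.atoms:
            self._by_residue.setdefault(a.residue_id(), []).append(a.atom_index)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def group(self, name: str) -> frozenset[int]:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"topology has no group named {name!r}") from None

    def residues_of(self, group_name: str) -> list[tuple[str, int]]:
        """Residue ids touched by a group, in first-appearance order."""
        members = self.group(group_name)
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if a.atom_index in members:
                seen.setdefault(a.residue_id())
        return list(seen)

    def residue_atoms(self, residue_id: tuple[str, int]) -> list[int]:
        try:
            return list(self._by_residue[residue_id])
        except KeyError:
            raise AtomNotFoundError(
                f"no residue {residue_id[1]} on chain {residue_id[0]!r}"
            ) from None

    def residue_name_of(self, residue_id: tuple[str, int]) -> str:
        return self.atoms[self.residue_atoms(residue_id)[0]].residue_name

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def lj_sigmas_nm(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms], dtype=float)

    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)


@dataclass
class Frame:
    """One snapshot: N×3 coordinates in Å, optional orthorhombic box
    edge lengths in Å, time stamp in ps."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N×3 array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be three orthorhombic edge lengths")
            if not np.all(self.box > 0):
                raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with an analysis discard window.

    Frames with ``time < discard_before`` (ps) are excluded from every
    statistic, mirroring the convention of dropping an initial
    equilibration stretch before analysis.
    """

    frames: list[Frame]
    discard_before: float = 0.0

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if not any(t >= self.discard_before for t in times):
            raise ValueError("no frame survives the discard window")

    def __len__(self) -> int:
        return len(self.frames)

    def retained(self, stride: int = 1) -> list[Frame]:
        """Frames surviving the discard window, subsampled by ``stride``
        starting from the first retained frame."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        kept = [f for f in self.frames if f.time >= self.discard_before]
        if not kept:
            raise ValueError("no frame survives the discard window")
        return kept[::stride]

    def iter_retained(self, stride: int = 1) -> Iterator[Frame]:
        return iter(self.retained(stride))


@dataclass(frozen=True)
class ActivationCriteria:
    """Geometric activation markers for a GPCR.

    ``distance_atoms``: pair of (residue_index, atom_name) whose
    separation reports TM5/TM7 rearrangement; active when the distance
    is strictly below ``distance_threshold`` (Å).

    ``angle_atoms``: triple of (residue_index, atom_name), vertex in
    the middle, reporting the outward swing of TM6; active when the
    angle is strictly above ``angle_threshold`` (degrees).

    ``combine``: "and" (default) requires both markers, "or" either.
    """

    distance_atoms: tuple[tuple[int, str], tuple[int, str]]
    distance_threshold: float
    angle_atoms: tuple[tuple[int, str], tuple[int, str], tuple[int, str]]
    angle_threshold: float
    combine: str = "and"
    chain: Optional[str] = None

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0 or self.angle_threshold <= 0:
            raise ValueError("activation thresholds must be positive")
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")


@dataclass
class EnergyBreakdown:
    """Mean ± fluctuation of the ligand–receptor interaction energy.

    All energies kJ/mol.  ``per_frame`` rows are (time, coulomb, lj);
    ``per_residue`` maps residue id → (coulomb_mean, lj_mean) for the
    decomposition side chosen.  Fluctuations are per-frame standard
    deviations within the trajectory.
    """

    coulomb_mean: float
    lj_mean: float
    total_mean: float
    coulomb_sd: float
    lj_sd: float
    total_sd: float
    per_frame: list[tuple[float, float, float]]
    per_residue: dict[tuple[str, int], tuple[float, float]]
    decomposition_side: str = "receptor"


@dataclass
class ContactCensus:
    """Contact statistics of receptor residues against the ligand."""

    per_residue_occupancy: dict[tuple[str, int], float]
    mean_contact_count: float
    class_counts: dict[str, int]
    contacting_residues: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class RmsfResult:
    """Per-residue RMSF (Å) over a selection plus its sum."""

    per_residue_rmsf: dict[tuple[str, int], float]
    selection_sum: float


def validate_topology(topology: Topology) -> list[str]:
    """Check every Topology invariant; return human-readable violations.

    Reports rather than raises: an empty list means the topology is
    valid.  Checked rules: unique atom indices matching list order,
    non-negative LJ parameters, positive masses, resolvable group
    members, presence and disjointness of the ligand/receptor groups.
    """
    violations: list[str] = []
    n = len(topology.atoms)
    for pos, a in enumerate(topology.atoms):
        if a.atom_index != pos:
            violations.append(
                f"atom at position {pos} has atom_index {a.atom_index}; "
                "indices must be 0-based and match list order"
            )
        if a.lj_sigma < 0:
            violations.append(f"atom {pos} ({a.atom_name}): negative lj_sigma")
        if a.lj_epsilon < 0:
            violations.append(f"atom {pos} ({a.atom_name}): negative lj_epsilon")
        if a.mass <= 0:
            violations.append(f"atom {pos} ({a.atom_name}): non-positive mass")
    for gname, members in topology.groups.items():
        bad = sorted(i for i in members if i < 0 or i >= n)
        if bad:
            violations.append(
                f"group {gname!r}: unresolvable atom indices {bad} (topology has {n} atoms)"
            )
    for required in ("ligand", "receptor"):
        if required not in topology.groups:
            violations.append(f"required group {required!r} is missing")
    if "ligand" in topology.groups and "receptor" in topology.groups:
        overlap = sorted(topology.groups["ligand"] & topology.groups["receptor"])
        if overlap:
            violations.append(
                f"disjointness: ligand and receptor groups share atoms {overlap}"
            )
    return violations


def resolve_atom(
    topology: Topology,
    residue_index: int,
    atom_name: str,
    chain: Optional[str] = None,
) -> int:
    """Resolve (residue number, atom name[, chain]) to a 0-based atom index.

    Raises :class:`AtomNotFoundError` when nothing matches and
    :class:`AmbiguousSelectionError` when several atoms match and no
    chain narrows the selection down to one.
    """
    matches = [
        a.atom_index
        for a in topology.atoms
        if a.residue_index == residue_index
        and a.atom_name == atom_name
        and (chain is None or a.chain_id == chain)
    ]
    if not matches:
        where = f" on chain {chain!r}" if chain is not None else ""
        raise AtomNotFoundError(
            f"atom not found: residue {residue_index} atom {atom_name!r}{where}"
        )
    if len(matches) > 1:
        raise AmbiguousSelectionError(
            f"ambiguous selection: residue {residue_index} atom {atom_name!r} "
            f"matches {len(matches)} atoms; pass a chain id"
        )
    return matches[0]
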