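"""Readers and writers: multi-model PDB trajectories, the topology
sidecar JSON, and deterministic result tables.

The multi-model PDB is the one mandatory trajectory dialect (PDB 3.3
fixed columns, MODEL/ENDMDL delimited, optional CRYST1).  HETATM
records are accepted — the chelator-ion entity is non-standard — and
atoms present in a file but in neither the ligand nor the receptor
group (waters, lipids, ions) are retained in frames and ignored by the
analyses.  Parsing is delegated to biotite; this module owns the
contract: ragged models and malformed records raise typed errors, and
a CRYST1 cell is accepted as a box only when orthorhombic.

The topology sidecar is a small versioned JSON carrying per-atom
charges, LJ parameters, masses and the named group selections — the
force-field-derived inputs the analyses consume but a PDB cannot hold.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
from biotite import InvalidFileError
from biotite.structure.io.pdb import PDBFile

from .model import (
    AtomRecord,
    ContactCensus,
    EnergyBreakdown,
    Frame,
    RmsfResult,
    Topology,
    Trajectory,
    validate_topology,
)

__all__ = [
    "RaggedTrajectoryError",
    "PdbParseError",
    "TopologySchemaError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_topology",
    "write_topology",
    "write_results",
    "TOPOLOGY_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

TOPOLOGY_SCHEMA_VERSION = 1


class RaggedTrajectoryError(ValueError):
    """Atom count differs between models of a multi-model PDB."""


class PdbParseError(ValueError):
    """Malformed ATOM/HETATM record or otherwise unreadable PDB."""


class TopologySchemaError(ValueError):
    """Topology sidecar does not match the expected JSON schema."""


def _box_from_biotite(box_matrix: Optional[np.ndarray]) -> Optional[np.ndarray]:
    """Orthorhombic edge lengths from a biotite 3×3 box, or None (with a
    warning) when the cell is not orthorhombic."""
    if box_matrix is None:
        return None
    off_diag = box_matrix - np.diag(np.diag(box_matrix))
    if np.any(np.abs(off_diag) > 1e-4):
        logger.warning(
            "CRYST1 cell is not orthorhombic; proceeding without a box"
        )
        return None
    edges = np.diag(box_matrix).astype(float)
    if np.any(edges <= 0):
        return None
    return edges


def read_multimodel_pdb(
    path: Union[str, Path], dt: float = 1.0, discard_before: float = 0.0
) -> tuple[Trajectory, list[dict[str, Any]]]:
    """Read a multi-model PDB into a Trajectory plus an atom identity
    table.

    One Frame per MODEL (a file without MODEL records is a single
    implicit model); coordinates in Å; frame times assigned as
    ``0, dt, 2·dt, …`` ps.  The identity table rows carry atom_name,
    element, residue_index, residue_name and chain_id in file order,
    for cross-checking against a topology sidecar.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except InvalidFileError as exc:
        if "must be equal" in str(exc):
            raise RaggedTrajectoryError(f"{path}: {exc}") from exc
        raise PdbParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise PdbParseError(f"{path}: unparseable coordinate record ({exc})") from exc
    box = _box_from_biotite(None if stack.box is None else stack.box[0])
    frames = [
        Frame(coordinates=np.asarray(stack.coord[m], dtype=float), box=box,
              time=m * dt)
        for m in range(stack.stack_depth())
    ]
    identity = [
        {
            "atom_name": str(stack.atom_name[i]),
            "element": str(stack.element[i]),
            "residue_index": int(stack.res_id[i]),
            "residue_name": str(stack.res_name[i]),
            "chain_id": str(stack.chain_id[i]),
        }
        for i in range(stack.array_length())
    ]
    return Trajectory(frames=frames, discard_before=discard_before), identity


def write_multimodel_pdb(
    trajectory: Trajectory,
    topology: Topology,
    path: Union[str, Path],
) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame).

    Atom identity comes from the topology; non-element pseudo-atoms are
    written as HETATM carbon-like records so the file stays standard.
    """
    n = topology.n_atoms
    coords = np.stack([f.coordinates for f in trajectory.frames]).astype(np.float32)
    if coords.shape[1] != n:
        raise ValueError("frame atom count does not match topology")
    stack = struc.AtomArrayStack(coords.shape[0], n)
    stack.coord = coords
    stack.chain_id = np.array([a.chain_id for a in topology.atoms])
    stack.res_id = np.array([a.residue_index for a in topology.atoms])
    stack.res_name = np.array([a.residue_name for a in topology.atoms])
    stack.atom_name = np.array([a.atom_name for a in topology.atoms])
    element = np.array(
        [a.element if a.element.upper() != "X" else "C" for a in topology.atoms]
    )
    stack.element = element
    stack.set_annotation(
        "hetero",
        np.array([a.residue_name not in _STANDARD_RESIDUES for a in topology.atoms]),
    )
    boxes = [f.box for f in trajectory.frames]
    if boxes[0] is not None:
        stack.box = np.stack([np.diag(b) for b in boxes]).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_ATOM_FIELDS = (
    "atom_index", "atom_name", "element", "residue_index", "residue_name",
    "chain_id", "charge", "lj_sigma", "lj_epsilon", "mass",
)


def read_topology(path: Union[str, Path]) -> Topology:
    """Read and validate a topology sidecar JSON.

    Raises :class:`TopologySchemaError` on a schema-version or field
    mismatch and :class:`ValueError` listing the violations when the
    topology's own invariants fail.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema_version") != TOPOLOGY_SCHEMA_VERSION:
        raise TopologySchemaError(
            f"{path}: expected schema_version {TOPOLOGY_SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}"
        )
    atoms = []
    for k, rec in enumerate(doc.get("atoms", [])):
        missing = [f for f in _ATOM_FIELDS if f not in rec]
        if missing:
            raise TopologySchemaError(f"{path}: atom {k} missing fields {missing}")
        atoms.append(AtomRecord(**{f: rec[f] for f in _ATOM_FIELDS}))
    groups = {
        name: frozenset(int(i) for i in members)
        for name, members in doc.get("groups", {}).items()
    }
    topology = Topology(atoms=atoms, groups=groups)
    violations = validate_topology(topology)
    if violations:
        raise ValueError(
            f"{path}: invalid topology: " + "; ".join(violations)
        )
    return topology


def write_topology(topology: Topology, path: Union[str, Path]) -> None:
    """Serialize a Topology to the sidecar JSON schema (sorted keys,
    deterministic output; round-trips field-identically)."""
    doc = {
        "schema_version": TOPOLOGY_SCHEMA_VERSION,
        "atoms": [asdict(a) for a in topology.atoms],
        "groups": {k: sorted(v) for k, v in sorted(topology.groups.items())},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# result tables


def _sig6(x: float) -> str:
    return f"{float(x):.6g}"


def _residue_label(rid: tuple[str, int]) -> str:
    return f"{rid[0]}:{rid[1]}"


def _rows_for(result: Any) -> tuple[list[str], list[list[str]]]:
    if isinstance(result, EnergyBreakdown):
        header = ["residue", "coulomb_mean", "lj_mean", "total_mean"]
        rows = [
            [_residue_label(rid), _sig6(c), _sig6(l), _sig6(c + l)]
            for rid, (c, l) in sorted(result.per_residue.items())
        ]
        return header, rows
    if isinstance(result, RmsfResult):
        header = ["residue", "rmsf_angstrom"]
        rows = [
            [_residue_label(rid), _sig6(v)]
            for rid, v in sorted(result.per_residue_rmsf.items())
        ]
        rows.append(["selection_sum", _sig6(result.selection_sum)])
        return header, rows
    if isinstance(result, ContactCensus):
        header = ["residue", "occupancy"]
        rows = [
            [_residue_label(rid), _sig6(v)]
            for rid, v in sorted(result.per_residue_occupancy.items())
        ]
        return header, rows
    if isinstance(result, Mapping):
        header = ["key", "value"]
        rows = [
            [str(k), _sig6(v) if isinstance(v, (int, float)) else str(v)]
            for k, v in sorted(result.items(), key=lambda kv: str(kv[0]))
        ]
        return header, rows
    raise TypeError(f"do not know how to tabulate {type(result).__name__}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (EnergyBreakdown, RmsfResult, ContactCensus)):
        obj = asdict(obj)
    if isinstance(obj, Mapping):
        return {
            (":".join(map(str, k)) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(_sig6(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def provenance_block(
    config: Optional[Mapping[str, Any]] = None,
    seed: Optional[int] = None,
    discard_before: Optional[float] = None,
) -> dict[str, Any]:
    """Provenance fields stamped into every result file: a stable hash
    of the configuration, the seed, and the discard window."""
    cfg_json = json.dumps(_jsonable(config or {}), sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": seed,
        "discard_before_ps": discard_before,
    }


def write_results(
    result: Any,
    path: Union[str, Path],
    format: str = "tsv",
    provenance: Optional[Mapping[str, Any]] = None,
) -> None:
    """Write a result object as TSV or JSON.

    Deterministic: fixed column order, sorted residue keys, floats at 6
    significant digits — writing the same object twice yields
    byte-identical files.  The provenance mapping (config hash, seed,
    discard window) is embedded as ``#``-comments (TSV) or a
    ``"provenance"`` key (JSON).
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown results format {format!r} (use 'tsv' or 'json')")
    prov = dict(provenance or {})
    buf = _io.StringIO()
    if format == "tsv":
        for k in sorted(prov):
            buf.write(f"# {k}: {prov[k]}\n")
        header, rows = _rows_for(result)
        buf.write("\t".join(header) + "\n")
        for row in rows:
            buf.write("\t".join(row) + "\n")
    else:
        doc = {"provenance": prov, "result": _jsonable(result)}
        json.dump(doc, buf, indent=1, sort_keys=True)
        buf.write("\n")
    Path(path).write_text(buf.getvalue())
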