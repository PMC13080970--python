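"""Packaged presets: activation-criteria files and the side-chain class
table.  Both are data, not code — residue numbering is
structure-specific, so analyses always take the criteria as input."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

from ..model import ActivationCriteria

__all__ = ["load_criteria", "load_class_table"]


def _read_packaged(name: str) -> dict:
    with resources.files(__package__).joinpath(name).open() as fh:
        return json.load(fh)


def load_criteria(
    source: Union[str, Path, Mapping, None] = None,
    chain: Optional[str] = None,
) -> ActivationCriteria:
    """Activation criteria from a JSON file, a mapping, or the packaged
    SSTR2 default when ``source`` is None."""
    if source is None:
        doc = _read_packaged("sstr2_default.json")
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    return ActivationCriteria(
        distance_atoms=tuple((int(r), str(n)) for r, n in doc["distance_atoms"]),
        distance_threshold=float(doc["distance_threshold"]),
        angle_atoms=tuple((int(r), str(n)) for r, n in doc["angle_atoms"]),
        angle_threshold=float(doc["angle_threshold"]),
        combine=doc.get("combine", "and"),
        chain=chain if chain is not None else doc.get("chain"),
    )


def load_class_table(source: Union[str, Path, None] = None) -> dict[str, str]:
    """Side-chain class table from JSON (``{"classes": {...}}``) or the
    packaged default."""
    doc = _read_packaged("residue_classes.json") if source is None else json.load(open(source))
    return {str(k).upper(): str(v) for k, v in doc["classes"].items()}
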