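"""End-to-end pipeline over replicate trajectories and system-to-system
comparison.

``run_pipeline`` executes every stage — activation classification,
interaction-energy decomposition, ECL2 RMSF, contact census, COM
penetration distances — over a bundle of replicates and aggregates:
active fractions are pooled frame-weighted (per-replicate values and
their spread are kept alongside), energies are reported with both
uncertainty conventions (per-frame sd within replicates, and sd across
replicate means), contact occupancies are pooled frame-weighted before
thresholding.  A stage failure is recorded under ``errors`` with the
stage name; the remaining stages still run.

The report is a plain nested dict, a pure function of (inputs, config):
serializing it with the io module's writers is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np

from .model import ActivationCriteria, Topology, Trajectory
from .activation import active_fraction, pooled_fraction
from .contacts import contact_census, com_distance_series
from .energetics import NonbondedConfig, trajectory_energy_series
from .geometry import rmsf
from .io import provenance_block, write_results, _jsonable
from .model import resolve_atom

__all__ = ["PipelineConfig", "Replicate", "run_pipeline", "compare_systems",
           "render_markdown_summary"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class Replicate:
    trajectory: Trajectory
    topology: Topology
    label: str = ""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the replicate bundle.

    ``ecl2_residues``: receptor residue numbers whose Cα RMSF is summed
    (the loop-closure statistic).  ``com_pairs`` maps a label to a pair
    of residue ids ((chain, resnum), (chain, resnum)).  ``discard_ps``
    overrides each trajectory's discard window when not None.
    """

    criteria: ActivationCriteria
    energy: NonbondedConfig = field(default_factory=NonbondedConfig)
    ecl2_residues: Sequence[int] = ()
    receptor_chain: str = "A"
    com_pairs: Mapping[str, tuple[tuple[str, int], tuple[str, int]]] = field(
        default_factory=dict
    )
    contact_cutoff: float = 3.0
    occupancy_threshold: float = 0.5
    heavy_atoms_only: bool = False
    stride: int = 1
    discard_ps: Optional[float] = None
    decomposition_side: str = "receptor"
    seed: Optional[int] = None

    def as_dict(self) -> dict[str, Any]:
        return {
            "criteria": {
                "distance_atoms": list(map(list, self.criteria.distance_atoms)),
                "distance_threshold": self.criteria.distance_threshold,
                "angle_atoms": list(map(list, self.criteria.angle_atoms)),
                "angle_threshold": self.criteria.angle_threshold,
                "combine": self.criteria.combine,
            },
            "energy": {
                "cutoff": self.energy.cutoff,
                "coulomb_constant": self.energy.coulomb_constant,
                "combination_rule": self.energy.combination_rule,
                "truncation": self.energy.truncation,
            },
            "ecl2_residues": list(self.ecl2_residues),
            "receptor_chain": self.receptor_chain,
            "com_pairs": {k: [list(a), list(b)] for k, (a, b) in self.com_pairs.items()},
            "contact_cutoff": self.contact_cutoff,
            "occupancy_threshold": self.occupancy_threshold,
            "heavy_atoms_only": self.heavy_atoms_only,
            "stride": self.stride,
            "discard_ps": self.discard_ps,
            "decomposition_side": self.decomposition_side,
            "seed": self.seed,
        }


def _ca_selection(topology: Topology, residues: Sequence[int], chain: str) -> list[int]:
    return [resolve_atom(topology, r, "CA", chain) for r in residues]


def _receptor_ca_selection(topology: Topology, chain: str) -> list[int]:
    members = topology.group("receptor")
    return [
        a.atom_index
        for a in topology.atoms
        if a.atom_index in members and a.atom_name == "CA" and a.chain_id == chain
    ]


def run_pipeline(
    replicates: Sequence[Replicate], config: PipelineConfig
) -> dict[str, Any]:
    """Run every analysis stage over a replicate bundle; return the
    report dict (see module docstring for aggregation conventions)."""
    if not replicates:
        raise ValueError("at least one replicate is required")
    for rep in replicates:
        if config.discard_ps is not None:
            rep.trajectory.discard_before = config.discard_ps
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": provenance_block(
            config.as_dict(),
            seed=config.seed,
            discard_before=config.discard_ps,
        ),
        "n_replicates": len(replicates),
        "errors": {},
    }
    try:
        frame_counts = [len(r.trajectory.retained(config.stride)) for r in replicates]
    except ValueError as exc:
        report["errors"]["frames"] = f"zero retained frames ({exc})"
        return report
    report["frame_counts"] = frame_counts

    # -- activation ---------------------------------------------------------
    try:
        fractions = []
        for rep in replicates:
            frac, _ = active_fraction(
                rep.trajectory, rep.topology, config.criteria, stride=config.stride
            )
            fractions.append(frac)
        pooled = pooled_fraction(fractions, frame_counts)
        report["activation"] = {
            "per_replicate": fractions,
            "pooled": pooled.pooled,
            "unweighted_mean": pooled.unweighted_mean,
            "range": list(pooled.range),
        }
    except Exception as exc:
        logger.exception("activation stage failed")
        report["errors"]["activation"] = str(exc)

    # -- energetics ---------------------------------------------------------
    try:
        breakdowns = [
            trajectory_energy_series(
                rep.trajectory, rep.topology, config.energy,
                stride=config.stride, side=config.decomposition_side,
            )
            for rep in replicates
        ]
        rep_means = np.array(
            [[b.coulomb_mean, b.lj_mean, b.total_mean] for b in breakdowns]
        )
        per_residue: dict[tuple[str, int], np.ndarray] = {}
        for b in breakdowns:
            for rid, (c, l) in b.per_residue.items():
                per_residue.setdefault(rid, np.zeros(2))
                per_residue[rid] += (c, l)
        nrep = len(breakdowns)
        report["energy"] = {
            "per_replicate": [
                {
                    "coulomb_mean": b.coulomb_mean, "coulomb_sd": b.coulomb_sd,
                    "lj_mean": b.lj_mean, "lj_sd": b.lj_sd,
                    "total_mean": b.total_mean, "total_sd": b.total_sd,
                }
                for b in breakdowns
            ],
            "replicate_mean": {
                "coulomb": float(rep_means[:, 0].mean()),
                "lj": float(rep_means[:, 1].mean()),
                "total": float(rep_means[:, 2].mean()),
            },
            "replicate_sd": {
                "coulomb": float(rep_means[:, 0].std()),
                "lj": float(rep_means[:, 1].std()),
                "total": float(rep_means[:, 2].std()),
            },
            "per_residue": {
                rid: [float(v[0] / nrep), float(v[1] / nrep)]
                for rid, v in per_residue.items()
            },
            "decomposition_side": config.decomposition_side,
        }
    except Exception as exc:
        logger.exception("energy stage failed")
        report["errors"]["energy"] = str(exc)

    # -- RMSF over ECL2 -----------------------------------------------------
    if config.ecl2_residues:
        try:
            sums = []
            per_res_acc: dict[tuple[str, int], float] = {}
            for rep in replicates:
                sel = _ca_selection(
                    rep.topology, config.ecl2_residues, config.receptor_chain
                )
                align = _receptor_ca_selection(rep.topology, config.receptor_chain)
                res = rmsf(rep.trajectory, rep.topology, sel, align, config.stride)
                sums.append(res.selection_sum)
                for rid, v in res.per_residue_rmsf.items():
                    per_res_acc[rid] = per_res_acc.get(rid, 0.0) + v
            report["rmsf"] = {
                "per_replicate_sum": sums,
                "sum_mean": float(np.mean(sums)),
                "sum_sd": float(np.std(sums)),
                "per_residue_mean": {
                    rid: v / len(replicates) for rid, v in per_res_acc.items()
                },
            }
        except Exception as exc:
            logger.exception("rmsf stage failed")
            report["errors"]["rmsf"] = str(exc)

    # -- contact census -----------------------------------------------------
    try:
        censuses = [
            contact_census(
                rep.trajectory, rep.topology,
                cutoff=config.contact_cutoff,
                occupancy_threshold=config.occupancy_threshold,
                stride=config.stride,
                heavy_atoms_only=config.heavy_atoms_only,
            )
            for rep in replicates
        ]
        # frame-weighted pooled occupancy, then threshold
        pooled_occ: dict[tuple[str, int], float] = {}
        total_frames = sum(frame_counts)
        for census, nf in zip(censuses, frame_counts):
            for rid, occ in census.per_residue_occupancy.items():
                pooled_occ[rid] = pooled_occ.get(rid, 0.0) + occ * nf / total_frames
        contacting = sorted(
            rid for rid, occ in pooled_occ.items()
            if occ >= config.occupancy_threshold
        )
        from .contacts import classify_residue  # late import avoids cycle at doc build

        class_counts: dict[str, int] = {}
        topo0 = replicates[0].topology
        for rid in contacting:
            cls = classify_residue(topo0.residue_name_of(rid))
            class_counts[cls] = class_counts.get(cls, 0) + 1
        report["contacts"] = {
            "pooled_occupancy": pooled_occ,
            "n_contacting": len(contacting),
            "contacting_residues": contacting,
            "class_counts": class_counts,
            "mean_contact_count": float(
                np.average([c.mean_contact_count for c in censuses],
                           weights=frame_counts)
            ),
        }
    except Exception as exc:
        logger.exception("contacts stage failed")
        report["errors"]["contacts"] = str(exc)

    # -- COM penetration distances -----------------------------------------
    if config.com_pairs:
        try:
            com: dict[str, Any] = {}
            for label, (rid_a, rid_b) in config.com_pairs.items():
                means, weights = [], []
                for rep, nf in zip(replicates, frame_counts):
                    _, mean = com_distance_series(
                        rep.trajectory, rep.topology,
                        tuple(rid_a), tuple(rid_b), stride=config.stride,
                    )
                    means.append(mean)
                    weights.append(nf)
                com[label] = {
                    "per_replicate_mean": means,
                    "pooled_mean": float(np.average(means, weights=weights)),
                }
            report["com_distances"] = com
        except Exception as exc:
            logger.exception("com stage failed")
            report["errors"]["com"] = str(exc)

    return report


_NOT_COMPARABLE = "not comparable"


def _pct_change(a: float, b: float) -> float:
    return float("nan") if a == 0 else 100.0 * (b - a) / abs(a)


def compare_systems(
    report_a: Mapping[str, Any], report_b: Mapping[str, Any]
) -> dict[str, Any]:
    """Δ and % change of the headline statistics between two reports.

    Sign convention (printed in the output): Δ = system B − system A,
    % change = 100·(B − A)/|A|.  A quantity missing from either report
    yields an explicit "not comparable" cell, never a failure.
    """
    out: dict[str, Any] = {
        "sign_convention": "delta = system_b - system_a; "
                           "pct_change = 100*(b - a)/abs(a)"
    }

    def scalar(report: Mapping[str, Any], *keys: str) -> Optional[float]:
        node: Any = report
        for k in keys:
            if not isinstance(node, Mapping) or k not in node:
                return None
            node = node[k]
        return float(node) if isinstance(node, (int, float)) else None

    quantities = {
        "active_fraction_pooled": ("activation", "pooled"),
        "energy_total_mean": ("energy", "replicate_mean", "total"),
        "energy_coulomb_mean": ("energy", "replicate_mean", "coulomb"),
        "energy_lj_mean": ("energy", "replicate_mean", "lj"),
        "rmsf_sum_mean": ("rmsf", "sum_mean"),
        "mean_contact_count": ("contacts", "mean_contact_count"),
        "n_contacting": ("contacts", "n_contacting"),
    }
    for name, keys in quantities.items():
        va, vb = scalar(report_a, *keys), scalar(report_b, *keys)
        if va is None or vb is None:
            out[name] = _NOT_COMPARABLE
        else:
            out[name] = {
                "a": va, "b": vb, "delta": vb - va, "pct_change": _pct_change(va, vb)
            }
    ca = report_a.get("contacts", {}).get("class_counts")
    cb = report_b.get("contacts", {}).get("class_counts")
    if isinstance(ca, Mapping) and isinstance(cb, Mapping):
        out["contact_class_counts"] = {
            cls: {"a": ca.get(cls, 0), "b": cb.get(cls, 0),
                  "delta": cb.get(cls, 0) - ca.get(cls, 0)}
            for cls in sorted(set(ca) | set(cb))
        }
    else:
        out["contact_class_counts"] = _NOT_COMPARABLE
    return out


def render_markdown_summary(report: Mapping[str, Any]) -> str:
    """Human-readable one-page summary of a pipeline report."""
    lines = ["# Trajectory analysis summary", ""]
    prov = report.get("provenance", {})
    lines.append(
        f"Config hash `{prov.get('config_sha256')}`, seed {prov.get('seed')}, "
        f"discard {prov.get('discard_before_ps')} ps; "
        f"{report.get('n_replicates')} replicate(s), "
        f"frames per replicate {report.get('frame_counts')}."
    )
    act = report.get("activation")
    if act:
        lines += [
            "",
            "## Activation",
            f"Pooled active fraction: {act['pooled']:.4f} "
            f"(per replicate: {['%.4f' % f for f in act['per_replicate']]}, "
            f"range {act['range'][0]:.4f}–{act['range'][1]:.4f})",
        ]
    en = report.get("energy")
    if en:
        m, s = en["replicate_mean"], en["replicate_sd"]
        lines += [
            "",
            "## Interaction energy (kJ/mol)",
            f"Total {m['total']:.6g} ± {s['total']:.3g} (sd across replicate means); "
            f"Coulomb {m['coulomb']:.6g}, LJ {m['lj']:.6g}.",
            "Per-replicate per-frame sd: "
            + ", ".join("%.3g" % r["total_sd"] for r in en["per_replicate"]),
        ]
    rm = report.get("rmsf")
    if rm:
        lines += [
            "",
            "## ECL2 RMSF",
            f"Selection sum: {rm['sum_mean']:.6g} Å "
            f"(per replicate {['%.4g' % v for v in rm['per_replicate_sum']]})",
        ]
    co = report.get("contacts")
    if co:
        lines += [
            "",
            "## Contact census",
            f"{co['n_contacting']} residues at occupancy threshold; "
            f"mean per-frame contact count {co['mean_contact_count']:.4g}; "
            f"classes {co['class_counts']}",
        ]
    cd = report.get("com_distances")
    if cd:
        lines += ["", "## COM distances (Å)"]
        for label, v in cd.items():
            lines.append(f"- {label}: pooled mean {v['pooled_mean']:.6g}")
    if report.get("errors"):
        lines += ["", "## Stage errors", str(report["errors"])]
    return "\n".join(lines) + "\n"
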