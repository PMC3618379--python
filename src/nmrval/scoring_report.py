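"""Per-residue red/orange/green roll-up and report assembly.

Every polymer residue receives a traffic-light verdict aggregating all the
evidence available for it: distance- and dihedral-restraint violations
(counted per constraint, in at least a configurable fraction of models so a
single flickering conformer cannot dominate), and chemical-shift Z-scores.
The trigger table (defaults in :class:`nmrval.config.RogThresholds`):

    red:    distance violation > 0.5 A in >= 50% of models, or
            dihedral violation > 20 deg in >= 50% of models, or
            any |z| > 5
    orange: distance violation > 0.3 A in >= 50% of models, or
            dihedral violation > 10 deg in >= 50% of models, or
            any 3 < |z| <= 5
    green:  nothing fired

Each verdict carries the list of triggers that fired, and the report embeds
the thresholds used, so scores are self-describing.  The full report is a
deterministic JSON document; see ``nmrval/data/report_schema.json``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import __version__ as _version
from .config import RogThresholds, ValidationConfig
from .model_io import Ensemble
from .restraint_validation import (ConstraintEnsembleStats, ViolationRecord,
                                   classify_distance_constraint)

logger = logging.getLogger(__name__)

ROG_LEVELS = ("green", "orange", "red")


@dataclass
class ResidueEvidence:
    """Everything the roll-up may look at for one residue."""

    chain: str
    resnum: int
    resname: str
    s2: float | None = None
    long_range_count: int = 0
    # per constraint touching this residue: id -> list of per-model magnitudes
    distance_magnitudes: dict[str, list[float]] = field(default_factory=dict)
    distance_classes: dict[str, str] = field(default_factory=dict)
    dihedral_magnitudes: dict[str, list[float]] = field(default_factory=dict)
    z_scores: list[float] = field(default_factory=list)
    near_aromatic: bool = False


def _fraction_exceeding(magnitudes: list[float], threshold: float) -> float:
    if not magnitudes:
        return 0.0
    return sum(1 for m in magnitudes if m > threshold) / len(magnitudes)


def residue_rog(evidence: ResidueEvidence,
                thresholds: RogThresholds | None = None) -> tuple[str, list[str]]:
    """Verdict and fired-trigger rationale for one residue.

    Worsening any single evidence item can only move the verdict toward
    red (monotone aggregation); with no evidence at all the residue is
    green.
    """
    t = thresholds or RogThresholds()
    red, orange = [], []
    for cid, mags in evidence.distance_magnitudes.items():
        if _fraction_exceeding(mags, t.red_dist_A) >= t.model_fraction:
            red.append(f"distance_violation_severe:{cid}")
        elif _fraction_exceeding(mags, t.orange_dist_A) >= t.model_fraction:
            orange.append(f"distance_violation:{cid}")
    for cid, mags in evidence.dihedral_magnitudes.items():
        if _fraction_exceeding(mags, t.red_dih_deg) >= t.model_fraction:
            red.append(f"dihedral_violation_severe:{cid}")
        elif _fraction_exceeding(mags, t.orange_dih_deg) >= t.model_fraction:
            orange.append(f"dihedral_violation:{cid}")
    for z in evidence.z_scores:
        if abs(z) > t.red_z:
            red.append("shift_outlier_severe")
        elif abs(z) > t.orange_z:
            orange.append("shift_outlier")
    if red:
        return "red", sorted(set(red)) + sorted(set(orange))
    if orange:
        return "orange", sorted(set(orange))
    return "green", []


# --------------------------------------------------------------------------
# evidence collection
# --------------------------------------------------------------------------

def _constraint_residues(constraint) -> set[tuple[str, int]]:
    out = set()
    for a, b in constraint.members:
        out.add((a[0], a[1]))
        out.add((b[0], b[1]))
    return out


def collect_evidence(ensemble: Ensemble, s2_map=None,
                     distance_constraints=None, distance_records=None,
                     dihedral_constraints=None, dihedral_records=None,
                     shift_records=None, lr_counts=None
                     ) -> dict[tuple[str, int], ResidueEvidence]:
    """Fold module outputs into one :class:`ResidueEvidence` per residue."""
    evidence = {}
    for chain, resnum, resname in ensemble.residues():
        evidence[(chain, resnum)] = ResidueEvidence(
            chain=chain, resnum=resnum, resname=resname,
            s2=(s2_map or {}).get((chain, resnum)),
            long_range_count=(lr_counts or {}).get((chain, resnum), 0))

    by_constraint: dict[str, list[float]] = {}
    for rec in distance_records or []:
        by_constraint.setdefault(rec.constraint_id, []).append(rec.magnitude)
    for con in distance_constraints or []:
        mags = by_constraint.get(con.id, [])
        cls = classify_distance_constraint(con, ensemble)
        for key in _constraint_residues(con):
            if key in evidence:
                evidence[key].distance_magnitudes[con.id] = mags
                evidence[key].distance_classes[con.id] = cls

    by_dihedral: dict[str, list[float]] = {}
    for rec in dihedral_records or []:
        by_dihedral.setdefault(rec.constraint_id, []).append(rec.magnitude)
    for con in dihedral_constraints or []:
        key = (con.chain, con.resnum)
        if key in evidence:
            evidence[key].dihedral_magnitudes[con.id] = by_dihedral.get(con.id, [])

    for rec in shift_records or []:
        key = (rec.chain, rec.resnum)
        if key in evidence:
            if rec.z is not None:
                evidence[key].z_scores.append(rec.z)
            evidence[key].near_aromatic |= rec.near_aromatic
    return evidence


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

def _violation_section(records: list[ViolationRecord] | None,
                       stats: list[ConstraintEnsembleStats] | None,
                       constraints, per_model: bool):
    section = []
    by_id = {}
    for rec in records or []:
        by_id.setdefault(rec.constraint_id, []).append(rec)
    for st in stats or []:
        entry = {
            "id": st.constraint_id,
            "range_class": st.range_class,
            "n_models": st.n_models,
            "n_violated": st.n_violated,
            "max_magnitude": st.max_magnitude,
            "mean_magnitude": st.mean_magnitude,
            "n_skipped": st.n_skipped,
        }
        if per_model:
            entry["per_model"] = [
                {"model": r.model_id, "actual": r.actual, "bound": r.bound,
                 "magnitude": r.magnitude} for r in by_id.get(st.constraint_id, [])]
        section.append(entry)
    return section


def assemble_report(ensemble: Ensemble, *, entry_id: str = "unknown",
                    config: ValidationConfig | None = None,
                    cluster_result=None, s2_map=None,
                    distance_constraints=None, distance_records=None,
                    distance_stats=None,
                    dihedral_constraints=None, dihedral_records=None,
                    dihedral_stats=None,
                    rdc_fits=None, rdc_stats=None, rdc_conventions=None,
                    shift_records=None, shift_offsets=None,
                    lr_counts=None, per_model: bool = False) -> dict:
    """Compose the final validation report dict.

    Absent data types produce empty sections; residue bookkeeping between
    sections is checked and a mismatch is a hard error.
    """
    config = config or ValidationConfig()
    evidence = collect_evidence(ensemble, s2_map, distance_constraints,
                                distance_records, dihedral_constraints,
                                dihedral_records, shift_records, lr_counts)
    expected = {(c, r) for c, r, _ in ensemble.residues()}
    if set(evidence) != expected:
        raise RuntimeError("residue bookkeeping mismatch between modules")

    residues, rog_section = [], []
    counts = {"red": 0, "orange": 0, "green": 0}
    for chain, resnum, resname in ensemble.residues():
        ev = evidence[(chain, resnum)]
        rog, rationale = residue_rog(ev, config.rog)
        counts[rog] += 1
        worst_dist = max((max(m, default=0.0)
                          for m in ev.distance_magnitudes.values()), default=0.0)
        worst_dih = max((max(m, default=0.0)
                         for m in ev.dihedral_magnitudes.values()), default=0.0)
        worst_z = max((abs(z) for z in ev.z_scores), default=None) \
            if ev.z_scores else None
        n_by_class = {c: 0 for c in ("intra", "short", "medium", "long")}
        for cid, mags in ev.distance_magnitudes.items():
            if any(m > 0 for m in mags):
                n_by_class[ev.distance_classes[cid]] += 1
        residues.append({
            "chain": chain, "resnum": resnum, "resname": resname,
            "s2": ev.s2,
            "n_distance_violations_by_class": n_by_class,
            "worst_distance_violation_A": worst_dist,
            "worst_dihedral_violation_deg": worst_dih,
            "worst_abs_z": worst_z,
            "long_range_count": ev.long_range_count,
            "near_aromatic": ev.near_aromatic,
            "rog": rog,
        })
        rog_section.append({"chain": chain, "resnum": resnum, "rog": rog,
                            "rationale": rationale})

    ens_section = {
        "n_models": ensemble.n_models,
        "chains": {c: {"n_residues": len(seq),
                       "polymer_type": ensemble.polymer_type[c]}
                   for c, seq in ensemble.sequence.items()},
    }
    if cluster_result is not None:
        ens_section["clusters"] = [
            {"members": sorted(members), "representative": rep}
            for members, rep in zip(cluster_result.clusters,
                                    cluster_result.representatives)]
        ens_section["representative_model"] = cluster_result.overall_representative

    rdc_section = []
    for medium in sorted(rdc_fits or {}):
        fits = rdc_fits[medium]
        per_con, summary = rdc_stats[medium] if rdc_stats else (None, None)
        entry = {
            "medium": medium,
            "convention": (rdc_conventions or {}).get(medium, "raw"),
            "models": [{
                "model": f.model_id,
                "tensor": f.tensor.matrix.tolist(),
                "da_hz": f.tensor.da_hz,
                "rhombicity": f.tensor.rhombicity,
                "axes": f.tensor.axes.T.tolist(),
                "rmsd_hz": f.rmsd_hz,
                "pearson_r": f.pearson_r,
                "q_value": f.q_value,
                "n_constraints": f.n_constraints,
                "degenerate": f.degenerate,
            } for f in fits],
        }
        if per_con is not None:
            entry["per_constraint"] = per_con
            entry["summary"] = summary
        rdc_section.append(entry)

    shifts_section = {
        "offsets_ppm": shift_offsets or {},
        "records": [{
            "chain": r.chain, "resnum": r.resnum, "resname": r.resname,
            "atom": r.atom, "nucleus_class": r.nucleus_class,
            "observed_ppm": r.observed_ppm, "offset_ppm": r.offset_ppm,
            "expected_mean_ppm": r.expected_mean_ppm,
            "expected_sd_ppm": r.expected_sd_ppm, "z": r.z,
            "outlier": r.outlier,
            "color": list(r.color) if r.color else None,
            "near_aromatic": r.near_aromatic,
        } for r in shift_records or []],
    }

    report = {
        "entry": {
            "id": entry_id,
            "generator": f"nmrval {_version}",
            "thresholds": config.to_dict(),
            "summary": {
                "n_residues": len(residues),
                "rog_counts": counts,
                "n_distance_constraints": len(distance_constraints or []),
                "n_dihedral_constraints": len(dihedral_constraints or []),
                "n_shift_outliers": sum(1 for r in shift_records or []
                                        if r.outlier),
            },
        },
        "ensemble": ens_section,
        "residues": residues,
        "distance_constraints": _violation_section(
            distance_records, distance_stats, distance_constraints, per_model),
        "dihedral_constraints": _violation_section(
            dihedral_records, dihedral_stats, dihedral_constraints, per_model),
        "rdc": rdc_section,
        "shifts": [shifts_section] if (shift_records or shift_offsets) else [],
        "rog": rog_section,
    }
    return report
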