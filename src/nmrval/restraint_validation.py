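"""Distance and dihedral restraint violation analysis.

Distance constraints are classified by sequence separation into
intra-residual (0), short (1-2), medium (3-4) and long-range (>= 5)
groups.  Ambiguous constraints (several candidate atom pairs, e.g. methyl
groups or unresolved assignments) are evaluated through the effective
distance

    d_eff = ( sum_p d_p^-6 )^(-1/6)

which is dominated by the closest member pair.  A constraint is violated in
a model when d_eff falls strictly outside the closed interval
[lower, upper]; dihedral constraints are violated when the angle lies
outside the counter-clockwise arc from lower to upper, with the magnitude
measured as the angular distance to the nearer arc endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensemble_analysis import DihedralSet
from .model_io import (DistanceConstraint, DihedralConstraint, Ensemble,
                       format_atom_ref)

logger = logging.getLogger(__name__)

RANGE_CLASSES = ("intra", "short", "medium", "long")


@dataclass
class ViolationRecord:
    constraint_id: str
    model_id: int
    actual: float          # d_eff (A) or angle (deg)
    bound: str             # "lower" | "upper" | "none"
    magnitude: float       # >= 0; 0 iff bound == "none"


@dataclass
class ConstraintEnsembleStats:
    constraint_id: str
    range_class: str | None
    n_models: int
    n_violated: int
    max_magnitude: float       # 0 when never violated
    mean_magnitude: float      # mean over violating models; 0 when none
    n_skipped: int = 0         # models where the quantity was undefined


def classify_distance_constraint(constraint: DistanceConstraint,
                                 ensemble: Ensemble) -> str:
    """Range class of a constraint: max sequence separation over member
    pairs; any inter-chain pair makes it long-range."""
    ref = ensemble.models[0]
    best = 0
    for a, b in constraint.members:
        for key in (a, b):
            if key not in ref.atoms:
                raise ValueError(
                    f"constraint {constraint.id}: atom "
                    f"{format_atom_ref(key)} not present in the ensemble")
        if a[0] != b[0]:
            return "long"
        best = max(best, abs(a[1] - b[1]))
    if best == 0:
        return "intra"
    if best <= 2:
        return "short"
    if best <= 4:
        return "medium"
    return "long"


def effective_distance(distances) -> float:
    """r^-6 sum-averaged effective distance: (sum d^-6)^(-1/6)."""
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one distance")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def _violation(actual: float, lower: float, upper: float) -> tuple[str, float]:
    if actual > upper:
        return "upper", actual - upper
    if actual < lower:
        return "lower", lower - actual
    return "none", 0.0


def evaluate_distance_constraints(constraints, ensemble: Ensemble):
    """Per-model violation records and per-constraint ensemble statistics.

    Returns ``(records, stats)`` where records is a flat list of
    :class:`ViolationRecord` (one per constraint per model) and stats one
    :class:`ConstraintEnsembleStats` per constraint.
    """
    records: list[ViolationRecord] = []
    stats: list[ConstraintEnsembleStats] = []
    for con in constraints:
        range_class = classify_distance_constraint(con, ensemble)
        magnitudes = []
        for model in ensemble.models:
            dists = [float(np.linalg.norm(model.position(a) - model.position(b)))
                     for a, b in con.members]
            d_eff = effective_distance(dists)
            bound, mag = _violation(d_eff, con.lower, con.upper)
            records.append(ViolationRecord(con.id, model.model_id, d_eff,
                                           bound, mag))
            if bound != "none":
                magnitudes.append(mag)
        stats.append(ConstraintEnsembleStats(
            constraint_id=con.id, range_class=range_class,
            n_models=ensemble.n_models, n_violated=len(magnitudes),
            max_magnitude=max(magnitudes, default=0.0),
            mean_magnitude=float(np.mean(magnitudes)) if magnitudes else 0.0))
    return records, stats


def angular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two angles in degrees (<= 180)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def dihedral_violation(theta: float, lower: float, upper: float) -> tuple[str, float]:
    """Check one angle against the counter-clockwise closed arc
    [lower -> upper]; wrap through +/-180 is permitted (lower > upper).

    Returns ("none", 0) when satisfied, otherwise the nearer endpoint
    ("lower" or "upper") and the angular distance to it.
    """
    span = (upper - lower) % 360.0
    pos = (theta - lower) % 360.0
    if pos <= span or span == 0.0 and pos == 0.0:
        return "none", 0.0
    d_lower = angular_distance(theta, lower)
    d_upper = angular_distance(theta, upper)
    if d_lower < d_upper:
        return "lower", d_lower
    return "upper", d_upper


def evaluate_dihedral_constraints(constraints, dset: DihedralSet):
    """Violation records and ensemble statistics for dihedral constraints.

    Models in which the constrained angle is undefined are skipped and
    counted in ``n_skipped``.
    """
    records: list[ViolationRecord] = []
    stats: list[ConstraintEnsembleStats] = []
    for con in constraints:
        values = dset.residue_angles(con.chain, con.resnum).get(con.angle)
        magnitudes = []
        n_skipped = 0
        n_eval = 0
        for model_idx in range(dset.n_models):
            theta = values[model_idx] if values is not None else None
            if theta is None:
                n_skipped += 1
                logger.warning("constraint %s: angle %s undefined for %s/%d in "
                               "model %d; skipped", con.id, con.angle, con.chain,
                               con.resnum, model_idx + 1)
                continue
            n_eval += 1
            bound, mag = dihedral_violation(theta, con.lower, con.upper)
            records.append(ViolationRecord(con.id, model_idx + 1, theta, bound,
                                           mag))
            if bound != "none":
                magnitudes.append(mag)
        stats.append(ConstraintEnsembleStats(
            constraint_id=con.id, range_class=None, n_models=dset.n_models,
            n_violated=len(magnitudes),
            max_magnitude=max(magnitudes, default=0.0),
            mean_magnitude=float(np.mean(magnitudes)) if magnitudes else 0.0,
            n_skipped=n_skipped))
    return records, stats


def long_range_counts(constraints, ensemble: Ensemble) -> dict[tuple[str, int], int]:
    """Number of long-range distance constraints touching each residue.

    Each long-range constraint increments the count of every residue that
    participates in any of its member pairs, once per constraint per
    residue.  Residues never touched get count 0.
    """
    counts = {(c, r): 0 for c, r, _ in ensemble.residues()}
    for con in constraints:
        if classify_distance_constraint(con, ensemble) != "long":
            continue
        residues = set()
        for a, b in con.members:
            residues.add((a[0], a[1]))
            residues.add((b[0], b[1]))
        for key in residues:
            if key in counts:
                counts[key] += 1
    return counts


def class_counts(constraints, ensemble: Ensemble) -> dict[str, int]:
    """Number of constraints per range class."""
    out = {c: 0 for c in RANGE_CLASSES}
    for con in constraints:
        out[classify_distance_constraint(con, ensemble)] += 1
    return out
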