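"""End-to-end validation pipeline: the programmatic equivalent of the
``nmrval validate`` command.

Runs, on whatever inputs are provided: ensemble clustering and
representative selection, per-residue order parameters, distance/dihedral
violation analysis, per-medium RDC tensor fits with unit-convention
detection, chemical-shift re-referencing and Z-scoring, and the ROG
roll-up — then assembles the JSON-ready report.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .config import ValidationConfig
from .ensemble_analysis import (cluster_and_represent,
                                compute_backbone_dihedrals, order_parameters)
from .model_io import Ensemble, read_constraint_table, read_ensemble, \
    read_shift_reference
from .rdc_analysis import (detect_rdc_unit_convention, ensemble_rdc_stats,
                           fit_ensemble)
from .restraint_validation import (evaluate_dihedral_constraints,
                                   evaluate_distance_constraints,
                                   long_range_counts)
from .scoring_report import assemble_report
from .shift_validation import (all_offsets, aromatic_proximity,
                               residue_environments, shift_zscores)

logger = logging.getLogger(__name__)


def run_validation(coordinates: str | Path | Ensemble, *,
                   distance_restraints=None, dihedral_restraints=None,
                   rdcs=None, shifts=None, shift_reference=None,
                   config: ValidationConfig | None = None,
                   entry_id: str | None = None,
                   per_model: bool = False) -> dict:
    """Validate an ensemble against all supplied data; return the report.

    Path-like arguments are read through :mod:`nmrval.model_io`; already
    parsed objects (an :class:`Ensemble`, lists of constraint records, a
    :class:`ShiftReferenceTable`) are accepted as well.
    """
    config = config or ValidationConfig()
    if isinstance(coordinates, Ensemble):
        ensemble = coordinates
        entry_id = entry_id or "ensemble"
    else:
        ensemble = read_ensemble(coordinates)
        entry_id = entry_id or Path(coordinates).stem

    def load(arg, kind):
        if arg is None:
            return None
        if isinstance(arg, (str, Path)):
            return read_constraint_table(arg, kind)
        return arg

    distance_constraints = load(distance_restraints, "distance")
    dihedral_constraints = load(dihedral_restraints, "dihedral")
    rdc_constraints = load(rdcs, "rdc")
    shift_records_in = load(shifts, "shift")
    if isinstance(shift_reference, (str, Path)):
        shift_reference = read_shift_reference(shift_reference)

    cluster = cluster_and_represent(ensemble,
                                    rmsd_cutoff_A=config.rmsd_cluster_cutoff_A)
    rep = cluster.overall_representative
    dset = compute_backbone_dihedrals(ensemble)
    s2_map = order_parameters(ensemble, dset)

    dist_records = dist_stats = None
    lr_counts = None
    if distance_constraints:
        dist_records, dist_stats = evaluate_distance_constraints(
            distance_constraints, ensemble)
        lr_counts = long_range_counts(distance_constraints, ensemble)

    dih_records = dih_stats = None
    if dihedral_constraints:
        dih_records, dih_stats = evaluate_dihedral_constraints(
            dihedral_constraints, dset)

    rdc_fits = rdc_stats = rdc_conventions = None
    if rdc_constraints:
        by_medium: dict[str, list] = {}
        for c in rdc_constraints:
            by_medium.setdefault(c.medium, []).append(c)
        rep_model = next(m for m in ensemble.models if m.model_id == rep)
        rdc_conventions, prescaled = {}, {}
        for medium, cons in by_medium.items():
            conv, _qs = detect_rdc_unit_convention(cons, rep_model,
                                                   config.bond_table)
            rdc_conventions[medium] = conv
            prescaled[medium] = conv == "prescaled"
        rdc_fits = fit_ensemble(by_medium, ensemble, config.bond_table,
                                prescaled)
        rdc_stats = {m: ensemble_rdc_stats(f) for m, f in rdc_fits.items()}

    shift_records = shift_offsets = None
    if shift_records_in and shift_reference is not None:
        envs = residue_environments(ensemble, rep, config, dset)
        near = aromatic_proximity(ensemble, rep, config.aromatic_proximity_A)
        shift_offsets = all_offsets(shift_records_in, shift_reference, envs,
                                    config)
        shift_records = shift_zscores(shift_records_in, shift_reference, envs,
                                      shift_offsets, config, near)

    return assemble_report(
        ensemble, entry_id=entry_id, config=config, cluster_result=cluster,
        s2_map=s2_map,
        distance_constraints=distance_constraints,
        distance_records=dist_records, distance_stats=dist_stats,
        dihedral_constraints=dihedral_constraints,
        dihedral_records=dih_records, dihedral_stats=dih_stats,
        rdc_fits=rdc_fits, rdc_stats=rdc_stats,
        rdc_conventions=rdc_conventions,
        shift_records=shift_records, shift_offsets=shift_offsets,
        lr_counts=lr_counts, per_model=per_model)
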