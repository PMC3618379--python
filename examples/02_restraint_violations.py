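"""Distance and dihedral restraint violation analysis.

Generates a 20-residue, 10-model ensemble with one distance constraint
tightened 1.0 A below the true distance and one psi arc shifted 20 degrees
off the true angle, then shows that the violation engine finds exactly
those two and nothing else.
"""

from nmrval import (compute_backbone_dihedrals, evaluate_dihedral_constraints,
                    evaluate_distance_constraints, long_range_counts)
from nmrval.restraint_validation import class_counts
from nmrval.synthetic_fixtures import generate, preset_spec

data = generate(preset_spec("violations", seed=0))

counts = class_counts(data.distance_constraints, data.ensemble)
print("constraint classes:", counts)

_, dist_stats = evaluate_distance_constraints(data.distance_constraints,
                                              data.ensemble)
print("\nviolated distance constraints "
      f"(planted: {data.planted_distance_id}):")
for s in dist_stats:
    if s.n_violated:
        print(f"  {s.constraint_id} ({s.range_class}): violated in "
              f"{s.n_violated}/{s.n_models} models, "
              f"mean magnitude {s.mean_magnitude:.2f} A")

dset = compute_backbone_dihedrals(data.ensemble)
_, dih_stats = evaluate_dihedral_constraints(data.dihedral_constraints, dset)
print(f"\nviolated dihedral constraints (planted: {data.planted_dihedral_id}):")
for s in dih_stats:
    if s.n_violated:
        print(f"  {s.constraint_id}: violated in {s.n_violated}/{s.n_models} "
              f"models, mean magnitude {s.mean_magnitude:.1f} deg")

lr = long_range_counts(data.distance_constraints, data.ensemble)
touched = {k: v for k, v in lr.items() if v}
print(f"\nlong-range constraint counts per residue: {touched}")
# The planted magnitudes come back at ~1.0 A and ~20 deg (up to the small
# coordinate jitter the generator adds per model); every untouched
# constraint is satisfied because its bounds bracket the true geometry.
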