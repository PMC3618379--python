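"""Residual dipolar coupling analysis: Saupe tensor fits per model.

Simulates N-HN and CA-HA RDCs from a known alignment tensor (Da = 10 Hz,
R = 0.3) against a noise-free helix, fits one tensor per model, and checks
that the unit-convention detector recognizes the raw (unscaled) deposition.
"""

import numpy as np

from nmrval import SaupeTensor, detect_rdc_unit_convention, ensemble_rdc_stats
from nmrval.rdc_analysis import fit_ensemble
from nmrval.synthetic_fixtures import generate, preset_spec

data = generate(preset_spec("rdc", seed=0))
truth = SaupeTensor.from_matrix(data.saupe_tensor)
print(f"generating tensor: Da = {truth.da_hz:.3f} Hz, "
      f"R = {truth.rhombicity:.3f}")

model = data.ensemble.models[0]
convention, qs = detect_rdc_unit_convention(data.rdc_constraints, model)
print(f"deposition convention detected: {convention} "
      f"(Q raw {qs['q_raw']:.2e} vs prescaled {qs['q_prescaled']:.3f})")

fits = fit_ensemble({"m1": data.rdc_constraints}, data.ensemble)["m1"]
print("\nper-model fits:")
for f in fits:
    print(f"  model {f.model_id}: Da {f.tensor.da_hz:7.3f} Hz, "
          f"R {f.tensor.rhombicity:.3f}, rmsd {f.rmsd_hz:.2e} Hz, "
          f"Q {f.q_value:.2e}, Pearson {f.pearson_r:.6f}")

per_con, summary = ensemble_rdc_stats(fits)
print(f"\nensemble summary: mean Da {summary['mean_da_hz']:.3f} Hz, "
      f"mean Q {summary['mean_q']:.2e} over {summary['n_models']} models")
# With no noise every model reproduces the generating tensor to numerical
# precision (Q ~ 1e-15); on real data Q ~ 0.2-0.4 is typical for structures
# refined without RDCs.
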