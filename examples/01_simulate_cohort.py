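"""Simulate a randomized adjunctive-antibiotics trial with known ground truth.

Generates the default synthetic cohort (163 patients, two arms, visits at
0/2/8/14/26 months, 200 taxa), writes it out as plain TSVs, and reports
what the configured mediator and outcome models imply for the marginal
treatment effect.
"""

from pathlib import Path

import periomed as pm
from periomed.io import write_cohort

config = pm.CohortConfig(seed=42)
cohort = pm.generate_cohort(config)

out = Path("scratch/example_cohort")
write_cohort(cohort, out)

n_samples, n_taxa = cohort.count_table.shape
print(f"cohort: {config.n_patients} patients, {n_samples} samples, "
      f"{n_taxa} taxa -> {out}/")
print("arm sizes:",
      cohort.metadata.drop_duplicates("subject_id")["arm"]
      .value_counts().to_dict())
print("true response categories:",
      cohort.truth.subjects["category"].value_counts().sort_index().to_dict())

rr, se = pm.implied_total_effect(config, n_mc=100_000)
print(f"implied marginal treatment rate ratio: {rr:.3f} (MC se {se:.1e})")
print("-> the conditional defaults (direct RR 0.82, category RR 0.72, "
      "treatment OR 6.42) imply this stronger marginal effect; "
      "calibrate_total_effect() reconciles it with an observed total.")

calibrated = pm.calibrate_total_effect(config, target_rr=0.73)
rr_cal, _ = pm.implied_total_effect(calibrated, n_mc=100_000, seed=1)
print(f"after calibration: category log-RR "
      f"{calibrated.outcome_model.category_log_rr:.4f} "
      f"-> implied total {rr_cal:.3f}")
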