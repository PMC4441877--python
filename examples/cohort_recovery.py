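"""Synthetic patient-level cohort: generate, aggregate, and feed back.

Simulates 10,000 patients over a four-week window, recovers the three
cohort-level inputs the deterministic model needs (mean attack rate,
pain-relief rate, mean frequency reduction), and re-runs the model on
the recovered values to show the patient-level and expectation-level
descriptions agree.
"""

import dataclasses

from spgcea import (
    aggregate_cohort,
    clinical_params_from_summary,
    default_params,
    run_model,
    simulate_cohort,
)

params = default_params()
patients = simulate_cohort(10_000, window_days=28.0, clinical=params.clinical, seed=42)
summary = aggregate_cohort(patients)

print(f"simulated {summary.n_patients} patients over 28 days")
print(f"  mean baseline rate   {summary.mean_baseline_rate:.3f} attacks/day "
      f"(model input 2.740)")
print(f"  pain-relief rate     {summary.pain_relief_rate:.3f} (model input 0.671)")
print(f"  mean freq. reduction {summary.mean_freq_reduction:.3f} (model input 0.310)")

recovered = dataclasses.replace(params,
                                clinical=clinical_params_from_summary(summary))
base_icer = run_model(params).ce.icer
rec_icer = run_model(recovered).ce.icer
print(f"\nICER from recovered cohort parameters: {rec_icer:,.0f} EUR/QALY "
      f"(deterministic base case {base_icer:,.0f})")
print("Close agreement shows the cohort model's expectation arithmetic is "
      "consistent with an explicit patient-level simulation.")
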