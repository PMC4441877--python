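"""One-way sensitivity analysis: re-run every published scenario.

Each row overrides one parameter (or the horizon) and reports the ICER —
or dominance, when stimulation is both cheaper and more effective — and
the per-patient budget impact (cost difference, payer perspective).
"""

from spgcea import default_params, run_table4, summary_frame

results = run_table4(default_params())
print(summary_frame(results).to_string(index=False))
print("\n'SPG dominating' rows are scenarios where stimulation saves money "
      "outright while still adding QALYs; positive cost differences are the "
      "extra five-year spend per patient, bought at the quoted EUR/QALY.")
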