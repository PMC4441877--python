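# Base case: on-demand SPG stimulation vs medical management for chronic
# cluster headache, German statutory-health-insurance payer perspective,
# 2014 euros, 5-year horizon, costs and effects discounted at 3 %/yr.
horizon_years: 5.0
clinical:
  baseline_attacks_per_day: 2.74      # trial baseline mean (range 0.57-10)
  pain_relief_prob: 0.671             # attack aborted <=15 min, no rescue meds
  initial_freq_reduction: 0.31        # prophylactic effect, whole cohort, year 1
  annual_decline_fraction: 0.10       # relative loss of the initial effect per year
costs:
  # Attack-aborting medication stack (oxygen, zolmitriptan nasal,
  # sumatriptan s.c./nasal): EUR 4,447.54 per six months at 2.74
  # attacks/day, i.e. EUR 8,895.08/yr.  Stored per attack at full
  # precision (8,895.08 / (2.74 x 365.25)); prints as ~8.92 under the
  # costing study's 182-day half-year.
  med_cost_per_attack: 8.8881028393
  implant_drg: 5293.99                # G-DRG B17-B, inpatient implantation
  device_cost: 25000.00               # reimbursed neurostimulator
  imaging_cost: 400.00                # CT/DVT pre- and post-implant
  titration_visits_cost: 596.46       # 6 headache-center titration visits
  revision_drg: 5293.99
  revision_prob: 0.125                # 4 of 32 patients
  revision_device_paid_by_payer: false  # replacement device supplied free by manufacturer
  antibiotics_cost: 94.88             # oral antibiotics, surgical-site infection
  infection_prob: 0.09375             # 3 of 32 patients
  explant_cost: 355.77                # outpatient explantation
  explant_prob: 0.0625                # 2 of 32 patients
utility:
  baseline_utility: 0.548             # control arm, constant over the horizon
  # Stimulation arm, mapped EQ-5D index vs months since implant.  The end
  # of the experimental phase and the open-label observation carry no
  # exact calendar time in the source trial report; 6 and 9 months are the
  # package's placement (see docs/methods.md).
  spg_utility_points:
  - [0.0, 0.548]
  - [6.0, 0.668]
  - [9.0, 0.675]
  - [12.0, 0.614]
  - [15.0, 0.606]
  - [18.0, 0.602]
  - [21.0, 0.592]
  - [24.0, 0.683]
  # Calibrated undiscounted QALY gain per model year (year 1, then years
  # 2+; years beyond the list reuse the last entry).
  annual_qaly_gain: [0.086, 0.066, 0.066, 0.066, 0.066]
  extrapolation_rule: year2-average
discount:
  annual_rate: 0.03
  cycle_length_days: 28.0
  timing: end                 # recurring flows discounted at cycle ends
  stim_med_timing: midpoint   # stimulation-arm residual medication at cycle midpoints
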