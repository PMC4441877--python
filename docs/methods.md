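# Methods

`spgcea` implements a deterministic two-arm cohort model of on-demand
sphenopalatine ganglion (SPG) stimulation versus medical management for
chronic cluster headache (cCH), from the perspective of German statutory
health insurance in 2014 euros. This note records the model, its
assumptions, the numerical conventions, and the design choices made where
the published description left the design open.

## Model structure

Two simulated cohorts are followed over a fixed horizon (base case: 5
years). No mortality is modelled — patients are young, the horizon short,
and no survival difference between arms is expected — so both arms accrue
exactly the horizon in life-years and differ only in utility weights and
costs.

**Control arm (medical management).** Patients keep their baseline attack
frequency (2.74 attacks/day, cohort mean) for the whole horizon and treat
every attack with the standard abortive-medication mix (oxygen,
zolmitriptan nasal, sumatriptan s.c./nasal). Health-related quality of
life stays at the baseline EQ-5D index (0.548).

**Stimulation arm.** A one-time expected up-front cost is booked at time
zero:

    E[upfront] = implant DRG + device + imaging + titration visits
               + P(revision) x (revision DRG + device if payer-paid)
               + P(infection) x antibiotics
               + P(explant) x explant procedure

with complication probabilities taken as trial frequencies (4/32, 3/32,
2/32). The base case assumes the manufacturer supplies the replacement
device in revisions at no charge; a scenario flips that flag, which adds
exactly 0.125 × €25,000 = €3,125 to the expected up-front cost.

Attack frequency in the stimulation arm is reduced by a prophylactic
effect `f(y)` that starts at 31 % and declines as a yearly step function:

    f(y) = max(0, f0 x (1 - d x (y - 1))),   f0 = 0.31, d = 0.10

so year 1 carries the full effect and the effect is halved entering year
6. `d` is stored as a *relative* fraction of the initial effect (0.10,
i.e. 3.1 percentage points per year at f0 = 31 %): the low/high
frequency-response scenarios (15 %, 50 %) only reconcile with their
published cost differences if the absolute decline scales with the
initial effect (1.5 and 5 points/yr respectively). Of the residual
attacks, a fraction `p = 0.671` (the trial's acute pain-relief endpoint:
relief within 15 minutes without rescue medication) needs no medication;
the rest are treated exactly like control-arm attacks. Stimulation-arm
medication cost in year `y` is therefore

    C_med(y) = r x 365.25 x c x (1 - f(y)) x (1 - p)

with `r` the baseline daily attack rate and `c` the per-attack
medication cost.

**Per-attack medication cost.** The published medication budget is a
six-month stack of €4,447.54 (≈ €8,895/yr, quoted as €171/week). The
per-attack cost is stored at full precision, 8,895.08 / (2.74 × 365.25) =
€8.8881, rather than the rounded €8.92 print (which is the same stack
divided by a 182-day half-year). This matters: the incremental cost is a
small difference of ~€32k arm totals, and carrying the rounded per-attack
price shifts it by ~€130. Scenario overrides use the published per-attack
prices (€18.81 sumatriptan-only, €56.66 guideline-maximum) as given.

## QALYs

Control-arm utility is constant at 0.548. The stimulation arm has two
routes:

* **calibrated** (default): per-year undiscounted QALY gains of 0.086
  (year 1) and 0.066 (each later year) added to the baseline utility.
  These are the published calibration of the trial's mapped EQ-5D
  trajectory; years beyond the list reuse the last value, and a
  fractional final year prorates linearly.
* **interpolated**: piecewise-linear interpolation of the mapped EQ-5D
  observations (0.548 baseline, 0.668 end of the experimental phase,
  0.675 open label, 0.614/0.606/0.602/0.592/0.683 at 12–24 months),
  sampled in 4-week increments, constant beyond 24 months at the year-2
  time-average, integrated year by year.

The experimental-phase and open-label observations carry no exact
calendar time in the trial report; this package places them at 6 and 9
months, which makes the two routes agree to 0.001 QALY in year 1 and
0.002 in year 2 (tolerance 0.01; a larger divergence is logged, never
silently absorbed). The calibrated route is the default precisely because
that placement is a reconstruction: the published per-year gains are
authoritative, the interpolated route exists to exercise and check the
described procedure. Effectiveness overrides in scenarios deliberately do
**not** rescale the QALY stream — the published sensitivity analysis
holds the trial-derived utility gains fixed while varying cost-side
parameters, and the package reproduces that choice rather than
"correcting" it.

## Time grid and discounting

Flows accrue uniformly over 4-week cycles, split at model-year boundaries
so the yearly step functions apply exactly; the final partial cycle is
prorated. Each interval's flow is discounted by `(1+ρ)^-t` (ρ = 0.03/yr)
evaluated at a configurable point of the interval: start, midpoint, end,
or exact integration ("continuous"). Setting the cycle length to 365.25
days with start timing yields classic annual-start discounting; a zero
rate reproduces undiscounted totals bit-for-bit.

The published analysis does not state its discounting convention, so the
default was **calibrated to the published five-year totals**: recurring
flows (control-arm medication, both QALY streams) discount at cycle
*ends* — the published control total implies an annuity factor of
41,298 / 8,895.08 = 4.6428, which is the cycle-end factor to four
significant figures — while the stimulation arm's residual-medication
stream discounts at cycle *midpoints*, which reproduces the published
stimulation-arm total to within €1. A single uniform timing cannot hit
both printed arm totals simultaneously (uniform midpoint gives an
incremental cost of ~€842, uniform end ~€878, against the printed €889);
the split default reproduces both arm totals and hence the printed
incremental cost almost exactly. Both timings are ordinary fields of
`DiscountSpec` for anyone preferring a uniform convention. Up-front costs
sit at t = 0 undiscounted; the trial-period timing of complication costs
(within year 1) is not modelled separately — discounting them inside year
1 would move results by well under 0.1 %.

Euros are carried at full precision throughout and rounded only at the
reporting boundary (`summary_frame`, CLI output): euros to integers,
QALYs to three decimals.

## Incremental analysis

For discounted arm totals, Δcost = cost_SPG − cost_control and ΔQALY
likewise; ICER = Δcost / ΔQALY. Verdicts follow the cost-effectiveness
plane: cheaper-and-more-effective is "SPG dominating" (no ICER quoted, by
convention), dearer-and-less-effective is dominated, ΔQALY = 0 yields a
verdict without an ICER, and the cheaper-but-less-effective quadrant
reports the savings-per-QALY-forgone ratio as an ICER.

## Scenario engine and horizon sweep

The sensitivity table is a declarative list of 18 named override sets
(base, undiscounted, pain relief 50.2/80.5 %, attack rate ±50 %,
medication utilisation ±25 % — implemented as a per-attack price
multiplier, equivalent under the linear cost model — no/15 %/50 %
frequency response, no/double decline, sumatriptan-only, guideline-max,
payer-paid revision device, 3.5- and 7-year horizons). The horizon sweep
re-runs the model at arbitrary horizons; intermediate points (4, 4.5, 6
years…) are model outputs without published counterparts.

## Synthetic cohort generator

The generator produces patient-level records whose aggregation recovers
the three cohort-level inputs the deterministic model consumes. It
emulates:

* baseline attack rates: log-normal (σ = 0.7 on the log scale, a breadth
  choice — only the mean is identified by the source data) truncated to
  the observed range 0.57–10 attacks/day, with location calibrated by
  root-finding so the *truncated* mean equals 2.74;
* per-patient frequency reductions: Beta with mean 0.31 and concentration
  12 (dispersion is a free knob; patients at ≥30 % reduction are labelled
  frequency responders);
* attacks: homogeneous Poisson counts over the simulation window at the
  prophylactically thinned rate, uniform day indices;
* acute relief: independent Bernoulli(0.671) per stimulated attack.

Rates and reductions use stratified inverse-CDF sampling (shuffled
stratified uniforms), so cohort means converge at O(1/n): the ICER
amplifies relative error in the mean attack rate roughly thirty-fold
(Δcost is a small difference of large totals), and plain iid sampling at
n = 10,000 would leave ~20 % ICER noise where the stratified design
leaves the Bernoulli relief outcomes (~2 %) as the dominant error.

What the generator does *not* emulate: the source trial's randomised
sham-control phases, within-patient correlation of relief outcomes,
attack clustering in time (circadian/cluster-period structure), and any
real patient-level response distribution — only the cohort means are
identified, so passing recovery tests validate the aggregation logic,
not distributional realism.

## Problem sizes and determinism

The deterministic model runs in milliseconds (66 intervals per 5-year
run); the full sensitivity table is 18 runs. Cohort tests use n = 10,000
patients over a 28-day window (~0.5 M attacks, about a second). All
randomness flows through a single `numpy` `Generator` seeded per call;
the same seed reproduces the same cohort exactly.

## Known limitations

* The discounting default is a reverse-engineered calibration, not a
  published convention; uniform-timing alternatives are one field away
  and shift the incremental cost by up to ~€47 (≈5 %) at 5 years.
* Published euro figures are rounded to integers and carry a ~€12
  internal inconsistency between the two arms' printed totals, which
  bounds achievable agreement on small cost differences.
* Costs beyond the 2014 German setting (no inflation, no currency
  conversion, no DRG regrouping), societal/indirect costs, preventative
  medication (identical across arms), probabilistic sensitivity analysis
  and mortality are all out of scope.
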