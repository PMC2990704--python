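# Model description and methods

## Disease natural history

The model tracks each person's *worst* colorectal lesion through the
states: no lesion, nonadvanced adenoma (<10 mm tubular), advanced adenoma
(≥10 mm, or ≥25% villous / high-grade dysplasia), undiagnosed CRC,
diagnosed CRC (with stage I–IV), post-polypectomy, and dead.  There is no
multi-polyp bookkeeping: post-polypectomy is the shared "history" state,
and a history raises the annual new-adenoma probability (base case 0.038
vs 0.02).  Serrated/flat pathways and rapid interval cancers are not
modelled.

Cycle length is one year.  Within a cycle the event order is fixed:

1. background mortality, then cancer-specific mortality (diagnosed
   patients within five years of diagnosis);
2. screening activity, if any is due;
3. disease progression (one step per year) and, for undiagnosed cancer,
   symptomatic presentation;
4. ageing.

Mortality-first means a person cannot be diagnosed and die of that cancer
in the same cycle, and the year of death accrues no utility (no half-cycle
correction).

**Stage and survival.**  Stage is assigned only at diagnosis, drawn from
one of three detection-route distributions (symptomatic/unscreened,
stool-detected, structurally detected); preclinical stage progression is
not modelled, and the unobservable sojourn time is represented solely by
the annual symptomatic-presentation probability *q*.  Stage-specific
five-year mortality m₅ is converted to a constant annual hazard
h = 1 − (1 − m₅)^{1/5} applied for exactly five years after diagnosis;
compounding h for five cycles reproduces m₅ exactly (property-tested).
Survivors beyond the window are cured: background mortality and full
utility.  Undiagnosed cancer carries background mortality only, because
stage — and hence excess mortality — exists only from diagnosis onward.

**Background mortality.**  The two printed inputs are stratum means: an
annual death risk of 0.005 at ages 50–64 and 0.018 at 65–75.  Population
mortality is age-dependent, so the default schedule is a Gompertz curve
μ(a) = A·e^{B(a−50)} anchored so that its unweighted mean over ages 50–64
equals 0.005 and over 65–75 equals 0.018, extrapolated over the lifetime
(μ ≈ 0.079 at 85, 0.218 at 95).  A flat two-band alternative
(`structural.mortality_model = "stratum"`, ages above 75 reusing the 65–75
value) is retained for comparison; it implies >50% survival to age 100 and
pushes calibrated cancer diagnoses unrealistically late, which is why the
anchored curve is the default.

**Cohort.**  One cohort enters at age 50 with the younger stratum's
prevalences (0.171 nonadvanced, 0.038 advanced, 0.001 CRC); parameters
switch to the older stratum at the birthday entering 65.  The horizon is
capped at age 100 (survivors are censored; at 5% discounting the truncated
tail is negligible).

## Screening

Strategies: FOBT (low/high performance) and FIT (low/mid/high) annually,
fecal DNA every 3 years, flexible sigmoidoscopy and CT colonography (CTC)
every 5, colonoscopy every 10; all offered from age 50 to 75.  Adherence
is redrawn independently at every offer (no persistent never-screener
class): 0.68 at the first offer, 0.63 subsequently, 0.81 for follow-up
colonoscopy after a positive test.  Test performance is per person
(sensitivity by lesion class; specificity against any positive).

The cascade rules, and the conventions chosen where the behaviour is
genuinely open:

- A positive stool test/CTC/flexible sigmoidoscopy leads to colonoscopy
  with probability 0.81; without follow-up the person simply stays on the
  routine schedule (no "known positive" tracking).
- All adenomas found at colonoscopy are removed.  Polypectomy schedules
  surveillance colonoscopy at 3 years (advanced adenoma, resected cancer)
  or 5 years (nonadvanced adenoma).  Routine screening continues between
  surveillance dates; a due surveillance colonoscopy takes precedence over
  a routine offer that year.  Missed surveillance (probability 0.19,
  reusing the follow-up adherence) is re-offered the next year.
- A clean *primary or follow-up* colonoscopy restarts the screening clock:
  10 years of exemption from routine offers
  (`structural.clean_colonoscopy_exemption_years`, configurable, 0
  disables).  A clean *surveillance* colonoscopy ends surveillance and
  returns the person to the routine schedule without an exemption.
- Flexible sigmoidoscopy's printed sensitivities already include lesions
  found at the completion colonoscopy of referred patients, so its
  referral colonoscopy detects the flagged lesion with certainty; the
  sigmoidoscope carries its own perforation risk (0.0002).
- CTC positives are referred to colonoscopy with a dedicated
  higher-sensitivity performance row.  A false-positive CTC (per-person
  specificity 0.89) produces a therapeutic colonoscopy; with probability
  0.41 (the <10 mm adenomatous-histology fraction) the removed polyp is
  treated as an adenoma finding — history flag and 5-year surveillance —
  otherwise the person is exempted as after any clean colonoscopy.  CTC
  perforation risk defaults to 0 and is never fatal.
- Colonoscopies that find cancer are costed as diagnostic (biopsy, not
  polypectomy); cancers found after a positive stool test take the
  stool-detected stage distribution, all others found at endoscopy/CTC the
  structural one.
- Complications: bleeding (0.0003 diagnostic / 0.005 therapeutic),
  perforation (0.0009 / 0.0024), death after endoscopic perforation 0.049.
- Diagnosed cancer patients leave the screening programme; their follow-up
  is part of cancer care.

## Economics

Costs are 2008 CAN$ from the publicly funded payer perspective plus
patient time/travel ("nonmedical") costs; productivity losses are
excluded.  Per event: stool kits CAN$12 (FOBT), 19 (FIT), 336 (fecal DNA)
plus 36 nonmedical; colonoscopy 857 diagnostic / 999 therapeutic plus 308;
CTC 582 + 105; flexible sigmoidoscopy 650 + 105; bleed 3,194; perforation
31,223; and the full stage-specific cancer-management cost (25,049 /
36,143 / 96,768 / 134,014 for stages I–IV) charged once in the diagnosis
year — no annual breakdown of treatment cost exists, so a lump sum at
diagnosis is the least-assumption choice.  An optional administrative cost
per *primary* screening test (default 0; scenarios use 10–50) models
programme overhead.  Utilities: 0.91 without cancer, 0.74 for stages I–II
and 0.46 for stages III–IV during the diagnosis year and the five-year
window, 0.91 for cured survivors.  Costs and utilities are discounted at
5%/year to the entry year.

## Engines

`run_microsim` samples persons one at a time through the per-person
functions.  Each person owns two RNG substreams (natural history,
screening) derived from `SeedSequence(entropy=(seed, person_index))`, so
results are independent of iteration order and setting all adherence to
zero reproduces the no-screening arm *exactly* under a common seed
(tested).

`run_cohort_expectation` propagates probability mass over an enumerated
state space — disease × surveillance countdown × routine-offer countdown ×
first-offer flag, plus stage × years-since-diagnosis for diagnosed
patients — and expands each screening encounter into analytic branches
(adherence × result × follow-up × detection × stage × perforation death).
Expected complication costs are attached unconditionally to each branch so
totals match the sampling engine's expectation exactly.  The two engines
are separate code paths; the suite checks their agreement within
Monte-Carlo standard errors, which caught a first-vs-subsequent adherence
inversion during development.

## Calibration

Published adenoma transition rates, applied unadjusted in this structure
over a lifetime horizon, yield ~10,600 lifetime cancers per 100,000 — far
above the reference no-screening burden of 4,857 cancers and 1,782 CRC
deaths per 100,000 that the model is meant to reproduce.  `calibrate`
therefore minimizes the summed squared relative error of the two
no-screening counts over five free parameters — the four transition
probabilities (bounded by their published plausible ranges) and the
symptomatic-presentation probability *q* (bounded [0.05, 0.95]) — using
Powell's derivative-free direction-set search on the deterministic
expectation engine (noise-free objective, ~240 evaluations, <1 s).  The
optimum sits essentially on the lower bounds (normal→nonadvanced 0.011,
nonadvanced→advanced 0.012, advanced→CRC 0.032, q ≈ 0.21).  The model's
deaths:cancers ratio is structurally ≈0.35 (stage mix × competing
mortality), slightly below the targets' 0.367, so the least-squares
optimum lands ~3% high on cancers and ~3% low on deaths;
`CalibrationResult.converged` applies a 2% criterion and is accordingly
False at the default targets, with the achieved counts reported alongside.

## Sensitivity analysis

Second-order PSA attaches distributions to every ranged probability and
cost input: beta (moment-matched, sd = quarter of the printed range) for
proportions, triangular (low, base as mode, high) for transition and
adherence probabilities, log-normal for costs.  Inputs without printed
ranges get conventional spreads chosen once: sd = 10% of the mean for
five-year mortality and stage costs, sd = 0.05 for utilities.  Test
sensitivity/specificity are never sampled — the two are linked through an
ROC curve and cannot vary independently — and the sampler rejects any such
path; test-performance uncertainty is explored through the discrete
strategy variants (FIT-low/mid/high etc.) instead.  Sampled draws are
repaired minimally to stay valid (stage rows renormalized; ordering
invariants restored by clipping).  Every strategy is evaluated on the same
draw, so incremental quantities are paired; intervals are empirical
2.5/97.5 percentiles with linear interpolation.

The scenario registry covers: biennial FIT, excluding biologic
chemotherapy (stage II/III/IV costs 35,844/80,345/99,574), +50% FIT cost,
differential first-offer adherence (0.60 FIT/fecal DNA, 0.50 FOBT, 0.40
CTC, 0.30 colonoscopy and flexible sigmoidoscopy), reduced subsequent
stool-test adherence (0.40, 0.20), administrative cost 10/30/50 per test,
and zeroed nonmedical costs.

## Incremental analysis

Strategies are sorted by ascending cost.  Strong dominance: some other
strategy costs no more and yields at least as many QALYs, one strictly.
Extended dominance: repeated peeling of any strategy whose ICER over its
cheaper frontier neighbour is ≥ the next ICER (equivalently, dominance by
a blend of two survivors; ties count as dominated, so frontier ICERs are
strictly increasing).  Both flags are reported separately.  Exact ties in
cost and effect are left undominated with a flagged, undefined ICER.  The
routine is tested against a brute-force oracle (exhaustive pairwise +
blend checks) on hundreds of random instances.

## What the tests do and do not show

The synthetic conditions are the base-case inputs themselves — the model
*is* the data-generating process — so the suite demonstrates internal
correctness (conservation, engine equivalence, closed forms, dominance,
schedule semantics) and reproduction of the reference burden after the
documented calibration.  It cannot validate the natural-history structure
against real registries.  Known reproduction limits, with the calibrated
base case:

- Lifetime counts (no-screening and FIT-mid cancers/deaths) match the
  reference values within ±10%.
- The calibrated rates sit at the lower bounds of their plausible ranges
  and q ≈ 0.21, which places diagnoses late in life.  Discounting then
  shrinks the cancer-treatment savings attributable to screening: the
  model makes annual FIT cost-*increasing* versus no screening by
  ~CAN$160/person rather than cost-saving, and yields a FIT-high vs
  FIT-mid ICER of ~CAN$102,000/QALY rather than ~85,000.  Both
  discrepancies trace to the same structural fact — the printed rate
  ranges cannot produce the reference burden with early-onset timing in a
  single-lesion state machine.
- Strategy ordering by cancer deaths matches the expected ranking except
  that flexible sigmoidoscopy and colonoscopy (≈2% apart) swap places.
- Absolute QALY levels (~14.5 discounted) exceed the reference (~11.3),
  consistent with the reference cohort including older entrants and/or a
  steeper real mortality schedule; incremental comparisons are less
  affected than levels.

## Numerical choices

- Discounting: amount/(1+r)^t with t = 0 in the entry year.
- Degenerate triangular ranges collapse to a point mass; beta parameters
  from mean/sd by moment matching with validity checks.
- Powell search: xtol 1e-4, bounded; an objective already < 1e-8 at the
  start returns the identity calibration.
- Monetary display values round to the nearest dollar and QALYs to three
  decimals in reports; all comparisons and stored values are unrounded.
- Strategy schedules (interval, start/stop age) live on
  `StrategyDefinition`; `StructuralSettings` carries the cohort entry age,
  horizon and discounting.
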