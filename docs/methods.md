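# Methods

## Model structure

The model is an incidence-based cost-of-illness decision tree. The unit
of analysis is one woman newly diagnosed with breast cancer in Germany
in 2015, classified as DCIS or invasive stage I–IV. Invasive cases are
partitioned into three mutually exclusive receptor subtypes (HR+, HER2+,
triple-negative) with stage-specific fractions; the subtype governs
endocrine-therapy and chemotherapy probabilities and the chemotherapy
course cost. Chance nodes are independent Bernoulli draws: surgery type
(BCS vs mastectomy, complementary), radiotherapy conditional on the
surgery type (82.6% after BCS, 27.6% after mastectomy, stage-invariant),
CT staging with a stage-specific indication share (0/0/48/100/100%),
chemotherapy-induced events conditional on chemotherapy (bisphosphonates
additionally restricted to stage IV), psychological care (36%),
transportation (100%), and death from breast cancer within the model
horizon (stage-specific probability `d_s`). DCIS patients receive only
diagnostics, surgery, post-surgical radiotherapy, psychological care,
and transportation, and never die of the disease in the base case.

Payoffs are monetary only (payer perspective, direct medical costs plus
travel; no discounting, no utilities, no indirect costs). Each received
component is charged once per course, except endocrine therapy, which is
an annual schedule: one first-year cycle (€1,181) plus
`duration_years − 1` later-year cycles (€757 each), defaulting to five
years total. Guideline practice ranges two to five years; the upper end
is the base case and values outside the 2–5 band only warn.

## Unit-cost uncertainty

Non-tariff unit costs are gamma-distributed with moment matching,
`shape = (mean/sd)²`, `scale = sd²/mean` — the only two-parameter gamma
link that reproduces both the mean and SD columns of the resource-use
table while keeping realized costs non-negative. Fixed administrative
tariffs (the diagnostic work-up items and the €145.73 CT examination)
have SD 0 and are charged exactly. Histopathology items are billed per
specimen; `specimen_count` defaults to 3, making the diagnostic bundle
62.07 + 4.56 + 99.79 + 32.15 + 3×10.79 + 3×11.79 + 150.85 = €417.16.
Draws are independent across components and patients; no correlation
structure is imposed.

## Phases of care

To compare against claims-data estimates, costs are attributed to
disease-management phases:

- **initial** — the first-year treatment bundle (diagnostics, CT,
  surgery, radiotherapy, first endocrine cycle, chemotherapy and induced
  events, psychological care, transportation) of women who do not die of
  breast cancer;
- **intermediate** — later-year endocrine cycles plus annual
  surveillance (one mammography + consultation visit, €66.63/year for
  `duration_years − 1` years) of surviving invasive patients;
- **terminal** — everything a decedent receives: the first-year bundle
  plus one palliative-care course (€11,976 mean), but no later-year
  endocrine cycles and no surveillance.

Phase expectations are conditional on the survival outcome, so the exact
identity `(1−d)(initial + intermediate) + d·terminal = stage cost` holds
per stage; an impossible conditioning set (e.g. terminal phase at d = 0)
has expectation zero. Because decedents never reach the later-year
cycles, the `hormone_therapy` component expectation carries the survival
weight on those cycles and `surveillance` is survival-weighted likewise;
this keeps the stage cost an exact sum of component expectations plus
death-weighted palliative care. Transportation is charged once, landing
in the initial phase for survivors and the terminal phase for decedents.

The intermediate phase deliberately covers incident-case surveillance
only. Claims-data benchmarks for that phase also absorb prevalent-case
follow-up and recurrence treatment, which this model excludes, so the
model's intermediate mean is a known underestimate and is not a
calibration target.

## Survival calibration

The stage-specific probabilities of dying of breast cancer within the
horizon are not public inputs; the shipped defaults — DCIS 0.0, I 0.10,
II 0.15, III 0.35, IV 0.85 over a 10-year horizon — are calibrations
anchored to the ~90% early-stage vs ~15% late-stage 5-year survival
contrast and checked against the published stage-wise cost means. They
are ordinary config parameters (`survival.death_probability`) and can be
overridden; validation enforces monotonicity in stage and warns if DCIS
is given a positive death probability.

## Synthetic cohorts

The generator emulates a registry-style incident census, not a survey
sample: per-stage counts are fixed quotas `round(scale × incidence)`
(half-away-from-zero, per stage), so only patient attributes are random.
All draws come from one numpy `Generator` in a documented order —
stage-major (DCIS → IV), component-major within stage in resource-table
order, patient-minor — and one uniform is consumed per patient per
chance node even when the node is unreachable, so stream alignment never
depends on parameter values and a fixed (seed, config-digest) pair
yields a bit-identical cohort. Cost realization uses a separate stream
(default `cohort.seed + 1`) and draws gammas only for set flags, in the
same documented order.

What the generator does **not** emulate: age structure, comorbidity,
recurrence and progression, calendar-time treatment drift, and any
correlation between treatment receipt and survival beyond the tree's
explicit conditioning. Passing tests therefore demonstrate internal
consistency of the model and faithful reproduction of the published
aggregate estimates, not agreement with individual-level real-world
claims trajectories.

## Sensitivity analysis

The one-way deterministic analysis recomputes an analytic outcome (no
Monte Carlo noise) at a lower and upper setting per scenario: every
treatment-proportion group swept to 0% and 100%; the surgery mix swept
all-BCS vs all-mastectomy; the survival table swept to 5-year and
15-year follow-up variants (base × 0.8 and base × 1.3 capped at 1 — a
calibration, since the underlying horizon-specific survival tables are
not public; both variants are overridable in config); and ±20% sweeps of
the main unit-cost means (SDs untouched — they do not enter the
analytic outcome). By linearity, a ±20% cost sweep has tornado range
exactly 0.4 × the component's expected cost, which the suite asserts to
1e-9 relative. Scenario settings are partial documents in the same YAML
dialect as the parameter file and are re-validated before any outcome is
computed.

Removing chemotherapy entirely (with its induced-event costs) cuts the
stage IV expected mean by roughly half, consistent with published
sensitivity statements for metastatic disease; for stages I–III the
reduction implied by the resource table is larger than the ~10%
sometimes quoted, so the package reports what the table implies rather
than forcing that figure. A config scenario restricted to discretionary
HR+ chemotherapy is expressible if the narrower reading is wanted.

## Numerical choices

- Probabilities are carried as fractions; configs carry them as
  percentages (as printed) and the serializer rounds the ×100
  conversion to 9 decimals so load → save → load round-trips exactly.
- 95% CIs use the normal approximation, mean ± 1.96·SD/√n, which
  reproduces the published interval bounds from their printed
  mean/SD/n to within €1; no t correction or bootstrap.
- Reported euro amounts are rounded only at the presentation layer;
  internal arithmetic is unrounded double precision.
- A single-record group reports SD 0 with a logged warning; empty
  groups are omitted with a warning rather than raised.
- Scaled cohorts require at least one patient per stage with positive
  incidence; a scale that empties a stage is rejected.
- Validation collects all findings before failing, reporting every
  violated key path at once.

## Problem sizes

The default test suite simulates the full 75,942-patient census (the
model's natural size; generation plus simulation take well under a
second) and uses 10⁶ draws per unit cost for distributional checks and
100,000 patients per stage in the headline reproduction script — sizes
chosen so Monte Carlo error is negligible relative to the 3-SE and 5%
bands used in the checks.

## Known limitations

- Incident cases only: surveillance of prevalent cases, recurrence, and
  progression costs are out of scope, so intermediate-phase and
  late-follow-up costs are underestimated by design.
- The variance of simulated per-stage costs mixes treatment-path
  heterogeneity with cost-draw variance in proportions that the
  published SDs do not pin down; the package reports its simulated SDs
  without forcing agreement.
- Inflation index factors are inputs; the package does not source
  official indices. The base case carries all costs already in 2021 EUR
  (identity series).
- Physician-visit costs, DRG/EBM tariff lookups beyond the configured
  unit costs, and quality-of-life or productivity effects are out of
  scope.
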