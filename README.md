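# bccost — stage-wise breast-cancer treatment costs for Germany

`bccost` is an incidence-based cost-of-illness model of breast cancer in
Germany. Claims data from the German statutory sickness funds carry no
tumour stage, so stage-wise direct medical costs cannot be measured from
billing records; this package estimates them instead with a decision-tree
model: every newly diagnosed woman of the 2015 incident cohort (75,942
cases: 6,050 DCIS, 27,866 stage I, 27,571 stage II, 8,692 stage III,
5,763 stage IV) walks a stage- and receptor-subtype-specific treatment
tree — diagnostic work-up, CT staging, breast-conserving surgery or
mastectomy, radiotherapy, endocrine therapy, chemotherapy with induced
adverse events, psychological care, transportation, and palliative care
for women dying of the disease — and accumulates component costs drawn
from gamma distributions (2021 EUR).

## Model

For a stage *s* with receptor-subtype mix *f(t|s)*, the expected
per-patient cost is the sum over care components *c* of

&nbsp;&nbsp;&nbsp;&nbsp;E[C(s)] = Σ_c Σ_t f(t|s) · P(c | s, t) · μ_c

where μ_c is the mean unit cost of the component's full course. Unit
costs are sampled as Gamma(k, θ) with moment matching, k = (μ/σ)²,
θ = σ²/μ, which keeps realized costs non-negative and reproduces both
the published mean and SD columns; σ = 0 marks fixed tariffs (KBV
diagnostic fees) that are charged exactly. Endocrine therapy runs one
first-year plus four later-year annual cycles; women dying of breast
cancer (stage-specific probability *d_s*) receive the first-year bundle
plus palliative care but no later-year cycles. Costs are attributed to
phases of care — initial (first-year bundle of survivors), intermediate
(later endocrine cycles + surveillance of survivors), terminal
(everything a decedent receives) — under the exact identity
(1−d)(initial+intermediate) + d·terminal = E[C(s)].

The package provides both evaluation routes: a closed-form expectation
engine (`bccost.expected`, also the outcome function of the tornado
sensitivity analysis) and a patient-level Monte Carlo simulator
(`bccost.simulate`) over synthetic registry-style cohorts
(`bccost.cohort`), plus reporting (`bccost.report`) and one-way
deterministic sensitivity analysis (`bccost.sensitivity`).

## Worked example

```python
import bccost
from bccost import Stage

params = bccost.default_parameters()          # shipped base case
print(round(bccost.expected_stage_cost(Stage.I, params)))    # 21553
print(round(bccost.expected_stage_cost(Stage.IV, params)))   # 41550
out = bccost.expected_cohort_cost(params)
print(round(out["per_incident_invasive"]))                   # 25653
print(round(out["phase_terminal_mean"]))                     # 36694
```

The stage I and IV values are the expected per-patient direct medical
costs (2021 EUR) over the model horizon; the per-incident-case figure is
the incidence-weighted mean over the invasive stages (DCIS is reported
separately, €9,168 expected). The same quantities can be simulated at
patient level from the command line:

```sh
bccost run --scale 0.05 --seed 7 --out demo/
```

writes `stage_summary.csv` (n, mean, SD, 95% CI, total per stage —
e.g. stage IV: n=288, mean €40,874, CI €37,763–€43,985 at this reduced
scale), `phase_summary.csv`, `percent_increase.csv` (stage means
relative to stage I), `component_shares.csv` (cost drivers; surgery and
chemotherapy including induced events carry ~63% of the invasive total),
a machine-readable `summary.json`, and a `manifest.json` recording the
config digest and seed. `bccost expected` writes the analytic tables
without sampling, and `bccost dsa` writes the tornado table of the
one-way sensitivity analysis.

## Layout

- `src/bccost/parameters.py` — config schema, validation, moment
  matching, inflation adjustment; `data/default_parameters.yaml` is the
  base case.
- `src/bccost/cohort.py` — synthetic incident cohorts with fixed
  per-stage quotas and reproducible decision-tree draws.
- `src/bccost/expected.py` — closed-form expectations by component,
  stage, and phase.
- `src/bccost/simulate.py` — gamma cost realization and phase
  attribution.
- `src/bccost/report.py` — summaries, CIs, national totals, cost-driver
  shares, external benchmark comparison (`data/benchmarks.csv`).
- `src/bccost/sensitivity.py` — scenario battery and tornado tables.
- `docs/methods.md` — modelling assumptions, calibrations, and
  limitations.
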