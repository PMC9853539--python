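# Base-case parameterization of the stage-wise breast-cancer cost model.
# Unit costs are in 2021 EUR (mean, SD); probabilities are percentages.
# Stage-wise incident case counts are the 2015 German registry census.
meta:
  price_year: 2021
  incidence_year: 2015
  seed: 20150

incidence:
  DCIS: 6050
  I: 27866
  II: 27571
  III: 8692
  IV: 5763

# Diagnostic work-up (KBV fixed tariffs, applied once to every diagnosed woman).
# Histopathology items are billed once per specimen; three specimens assumed.
diagnostics:
  specimen_count: 3
  items:
    - {name: mammography, cost: 62.07}
    - {name: consultation, cost: 4.56}
    - {name: clarification_imaging_biopsy, cost: 99.79}
    - {name: vacuum_biopsy_supplement, cost: 32.15}
    - {name: histopathology, cost: 10.79, per_specimen: true}
    - {name: histopathology_supplement, cost: 11.79, per_specimen: true}
    - {name: grading_immunohistochemistry, cost: 150.85}

# CT of chest and abdomen for node-positive disease / tumors >= T2, once at
# diagnosis; the stage proportion is the share of patients with that indication.
ct_staging:
  cost_mean: 145.73
  cost_sd: 0.0
  proportion_percent: {DCIS: 0.0, I: 0.0, II: 48.0, III: 100.0, IV: 100.0}

surgery:
  bcs: {cost_mean: 4640, cost_sd: 1855}
  mastectomy: {cost_mean: 7045, cost_sd: 2818}
  p_bcs_percent: {DCIS: 80, I: 92, II: 76, III: 11.6, IV: 11.6}
  p_mastectomy_percent: {DCIS: 20, I: 8, II: 24, III: 88.4, IV: 88.4}

# Radiotherapy after surgery, conditional on the surgical procedure.
radiotherapy:
  cost_mean: 1924
  cost_sd: 769
  p_after_bcs_percent: 82.6
  p_after_mastectomy_percent: 27.6

# Receptor-subtype mix of invasive stages (mutually exclusive, sums to 100).
subtype_fractions_percent:
  I: {HR_POS: 81.6, HER2_POS: 10.9, TN: 7.5}
  II: {HR_POS: 70.7, HER2_POS: 17.3, TN: 12.0}
  III: {HR_POS: 63.0, HER2_POS: 26.0, TN: 11.0}
  IV: {HR_POS: 61.0, HER2_POS: 28.4, TN: 10.6}

# Endocrine therapy: one first-year cycle plus (duration - 1) later-year
# cycles for treated patients who survive past the first year.
hormone_therapy:
  first_year: {cost_mean: 1181, cost_sd: 639}
  later_years: {cost_mean: 757, cost_sd: 402}
  duration_years: 5
  probability_percent:
    I: {HR_POS: 91.2, HER2_POS: 42.4, TN: 0.0}
    II: {HR_POS: 91.2, HER2_POS: 42.4, TN: 0.0}
    III: {HR_POS: 91.2, HER2_POS: 42.4, TN: 0.0}
    IV: {HR_POS: 49.0, HER2_POS: 49.0, TN: 0.0}

# Chemotherapy: probability and course cost per stage and subtype.
# HER2+ and TN disease is treated with certainty; HR+ chemotherapy is
# discretionary in stages I-III.
chemotherapy:
  I:
    HR_POS: {p_percent: 27.0, cost_mean: 6846, cost_sd: 2737}
    HER2_POS: {p_percent: 100.0, cost_mean: 28517, cost_sd: 11406}
    TN: {p_percent: 100.0, cost_mean: 6846, cost_sd: 2737}
  II:
    HR_POS: {p_percent: 27.0, cost_mean: 6846, cost_sd: 2737}
    HER2_POS: {p_percent: 100.0, cost_mean: 28517, cost_sd: 11406}
    TN: {p_percent: 100.0, cost_mean: 6846, cost_sd: 2737}
  III:
    HR_POS: {p_percent: 48.0, cost_mean: 6846, cost_sd: 2737}
    HER2_POS: {p_percent: 100.0, cost_mean: 28517, cost_sd: 11406}
    TN: {p_percent: 100.0, cost_mean: 6846, cost_sd: 2737}
  IV:
    HR_POS: {p_percent: 40.0, cost_mean: 13111, cost_sd: 5242}
    HER2_POS: {p_percent: 75.0, cost_mean: 52414, cost_sd: 20965}
    TN: {p_percent: 85.0, cost_mean: 20592, cost_sd: 8377}

# Chemotherapy-induced events; probabilities conditional on chemotherapy.
# Bisphosphonates are restricted to chemotherapy-treated stage IV patients.
adverse_events:
  neutropenic_sepsis: {p_percent: 15.0, cost_mean: 6213, cost_sd: 2485}
  pegfilgrastim: {p_percent: 50.0, cost_mean: 10586, cost_sd: 4235}
  antiemetics: {p_percent: 100.0, cost_mean: 531, cost_sd: 212}
  bisphosphonates: {p_percent: 100.0, cost_mean: 452, cost_sd: 181, stages: [IV]}
  lymph_drainage: {p_percent: 25.0, cost_mean: 1590, cost_sd: 636}

# End-of-life care for every woman dying of breast cancer.
palliative_care: {cost_mean: 11976, cost_sd: 4791}

psychological: {p_percent: 36.0, cost_mean: 1322, cost_sd: 528}

transportation: {p_percent: 100.0, cost_mean: 1776, cost_sd: 2682}

# Annual surveillance visit (mammography 62.07 + consultation 4.56) for
# surviving invasive patients, charged for (duration_years - 1) years.
surveillance:
  annual_cost: 66.63

# Probability of dying of breast cancer within the model horizon.  These are
# calibrated defaults (the stage-wise survival tables behind the model are
# not public): ~90% early-stage vs ~15% late-stage 5-year survival.
survival:
  horizon_years: 10
  death_probability: {DCIS: 0.0, I: 0.10, II: 0.15, III: 0.35, IV: 0.85}

inflation:
  base_year: 2021
  factors: {2021: 1.0}
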