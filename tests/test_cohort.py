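"""Synthetic incident cohorts: quotas, decision-tree draws, reproducibility."""
import numpy as np
import pandas as pd
import pytest

from bccost import Stage, Subtype, assign_treatments, generate_cohort
from bccost.cohort import Patient, patient_from_row
from bccost.parameters import ADVERSE_EVENT_COMPONENTS, Component


class TestQuotas:
    def test_full_scale_counts_are_the_census(self, params, full_cohort):
        counts = full_cohort.stage_counts()
        assert len(full_cohort) == 75942
        assert counts == params.incidence
        assert counts[Stage.IV] == 5763

    def test_scaled_counts_round_half_away_per_stage(self, params):
        cohort = generate_cohort(params, scale=0.01, seed=3)
        counts = cohort.stage_counts()
        # 60.5 -> 61, 278.66 -> 279, 275.71 -> 276, 86.92 -> 87, 57.63 -> 58
        assert counts == {
            Stage.DCIS: 61,
            Stage.I: 279,
            Stage.II: 276,
            Stage.III: 87,
            Stage.IV: 58,
        }

    def test_scale_out_of_range_rejected(self, params):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                generate_cohort(params, scale=bad)

    def test_scale_emptying_a_stage_rejected(self, params):
        with pytest.raises(ValueError, match="stage"):
            generate_cohort(params, scale=1e-5)


class TestStructuralInvariants:
    def test_dcis_patients_have_no_subtype_and_never_die(self, full_cohort):
        dcis = full_cohort.patients.query("stage == 'DCIS'")
        assert (dcis["subtype"] == "").all()
        assert not dcis["dies_of_bc"].any()
        for col in ("chemotherapy", "hormone_therapy", "ct_staging"):
            assert not dcis[col].any()

    def test_exactly_one_surgery_type(self, full_cohort):
        df = full_cohort.patients
        assert (df["bcs"] ^ df["mastectomy"]).all()

    def test_chemo_conditioning_of_adverse_events(self, full_cohort):
        df = full_cohort.patients
        no_chemo = df[~df["chemotherapy"]]
        for comp in ADVERSE_EVENT_COMPONENTS:
            assert not no_chemo[comp.value].any()

    def test_bisphosphonates_restricted_to_stage_iv(self, full_cohort):
        df = full_cohort.patients
        assert (df.loc[df["bisphosphonates"], "stage"] == "IV").all()
        iv_chemo = df.query("stage == 'IV' and chemotherapy")
        assert iv_chemo["bisphosphonates"].all()  # probability is 100%

    def test_palliative_iff_dying_and_transport_universal(self, full_cohort):
        df = full_cohort.patients
        assert (df["palliative_care"] == df["dies_of_bc"]).all()
        assert df["transportation"].all()

    def test_zero_death_probability_is_degenerate(self, params):
        p = params.with_overrides(
            {"survival": {"death_probability": {"I": 0.0}}}
        )
        cohort = generate_cohort(p, scale=0.05, seed=7)
        stage1 = cohort.patients.query("stage == 'I'")
        assert not stage1["dies_of_bc"].any()


class TestSamplingDistributions:
    def test_subtype_mix_converges_to_partition(self, params, full_cohort):
        df = full_cohort.patients
        for stage in (Stage.I, Stage.II, Stage.III, Stage.IV):
            sub = df[df["stage"] == stage.value]
            n = len(sub)
            for t in Subtype:
                frac = params.subtype_fractions[stage][t]
                se = np.sqrt(frac * (1 - frac) / n)
                observed = (sub["subtype"] == t.value).mean()
                assert abs(observed - frac) < 3 * se

    def test_radiotherapy_conditional_on_surgery_type(self, params, full_cohort):
        df = full_cohort.patients
        for flag, p_true in (
            ("bcs", params.p_radio_after_bcs),
            ("mastectomy", params.p_radio_after_mastectomy),
        ):
            arm = df[df[flag]]
            se = np.sqrt(p_true * (1 - p_true) / len(arm))
            assert abs(arm["radiotherapy"].mean() - p_true) < 3 * se

    def test_death_rates_converge(self, params, full_cohort):
        df = full_cohort.patients
        for stage in (Stage.I, Stage.IV):
            sub = df[df["stage"] == stage.value]
            d = params.death_prob[stage]
            se = np.sqrt(d * (1 - d) / len(sub))
            assert abs(sub["dies_of_bc"].mean() - d) < 3 * se


class TestReproducibility:
    def test_same_seed_is_bit_identical(self, params):
        a = generate_cohort(params, scale=0.02, seed=11)
        b = generate_cohort(params, scale=0.02, seed=11)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        assert a.params_digest == b.params_digest

    def test_different_seed_differs(self, params):
        a = generate_cohort(params, scale=0.02, seed=11)
        b = generate_cohort(params, scale=0.02, seed=12)
        assert not a.patients.equals(b.patients)

    def test_csv_round_trip(self, params, tmp_path):
        from bccost.cohort import Cohort

        a = generate_cohort(params, scale=0.01, seed=5)
        path = tmp_path / "cohort.csv"
        a.to_csv(path)
        b = Cohort.from_csv(path)
        pd.testing.assert_frame_equal(
            a.patients.reset_index(drop=True), b.patients, check_dtype=False
        )


class TestPerPatientAssignment:
    def test_certain_treatments_are_certain(self, params, rng):
        # triple-negative early disease: chemotherapy probability 100%
        for i in range(25):
            p = Patient(id=i, stage=Stage.I, subtype=Subtype.TN, dies_of_bc=False)
            p = assign_treatments(p, params, rng)
            assert p.treatments[Component.CHEMOTHERAPY]
        # stage III: CT staging indicated for everyone
        for i in range(25):
            p = Patient(id=i, stage=Stage.III, subtype=Subtype.HR_POS, dies_of_bc=False)
            p = assign_treatments(p, params, rng)
            assert p.treatments[Component.CT_STAGING]

    def test_invasive_patient_without_subtype_rejected(self, params, rng):
        p = Patient(id=0, stage=Stage.II, subtype=None, dies_of_bc=False)
        with pytest.raises(ValueError, match="subtype"):
            assign_treatments(p, params, rng)

    def test_row_round_trip(self, params, full_cohort):
        row = full_cohort.patients.iloc[123]
        patient = patient_from_row(row)
        assert patient.id == row["patient_id"]
        assert patient.treatments[Component.BCS] == row["bcs"]
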