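"""Parameter loading, validation, moment matching, and inflation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bccost.parameters import (
    DETERMINISTIC,
    ParameterValidationError,
    Stage,
    Subtype,
    adjust_inflation,
    default_parameters,
    gamma_params,
    load_parameters,
    save_parameters,
    validate_parameters,
)


class TestLoading:
    def test_default_config_matches_resource_table(self, params):
        assert params.p_bcs[Stage.I] == pytest.approx(0.92)
        assert params.p_mastectomy[Stage.III] == pytest.approx(0.884)
        assert params.chemo_cost[Stage.IV][Subtype.HER2_POS].mean == 52414
        assert params.ct_proportion[Stage.II] == pytest.approx(0.48)
        assert params.subtype_fractions[Stage.II][Subtype.HR_POS] == pytest.approx(
            0.707
        )
        assert params.total_incidence == 75942
        # subtype partitions are exhaustive
        for s in (Stage.I, Stage.II, Stage.III, Stage.IV):
            assert sum(params.subtype_fractions[s].values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_diagnostic_bundle_applies_specimen_multiplier(self, params):
        assert params.diagnostics_cost == pytest.approx(417.16)

    def test_surgery_split_must_sum_to_one(self, params):
        cfg = params.to_config()
        cfg["surgery"]["p_bcs_percent"]["I"] = 100.0  # mastectomy still 8%
        with pytest.raises(ParameterValidationError, match="P\\(BCS\\)"):
            load_parameters(cfg)

    def test_all_violations_reported_together(self, params):
        cfg = params.to_config()
        cfg["surgery"]["p_bcs_percent"]["I"] = 130.0
        cfg["survival"]["death_probability"]["IV"] = 1.2
        with pytest.raises(ParameterValidationError) as err:
            load_parameters(cfg)
        paths = [f.path for f in err.value.findings]
        assert any("surgery" in p for p in paths)
        assert any("survival" in p for p in paths)

    def test_round_trip_is_identical(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        reloaded = load_parameters(path)
        assert reloaded == params
        assert reloaded.digest() == params.digest()

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            load_parameters("/nonexistent/params.yaml")


class TestValidateFindings:
    def test_default_config_is_clean(self, params):
        assert [f for f in validate_parameters(params) if f.severity == "error"] == []

    def test_death_probability_out_of_range_is_found(self, params):
        import dataclasses

        bad = dataclasses.replace(
            params, death_prob={**params.death_prob, Stage.IV: 1.2}
        )
        findings = validate_parameters(bad)
        assert any("survival" in f.path and f.severity == "error" for f in findings)

    def test_subtype_fractions_not_summing_found(self, params):
        import dataclasses

        frac = {k: dict(v) for k, v in params.subtype_fractions.items()}
        frac[Stage.II][Subtype.TN] = 0.07  # sums to 0.95
        bad = dataclasses.replace(params, subtype_fractions=frac)
        findings = validate_parameters(bad)
        assert any("subtype_fractions.II" in f.path for f in findings)


class TestGammaParams:
    @pytest.mark.parametrize(
        "mean,sd,shape,scale",
        [(4640, 1855, 6.2568, 741.60), (11976, 4791, 6.2477, 1916.88)],
    )
    def test_moment_matched_examples(self, mean, sd, shape, scale):
        got_shape, got_scale = gamma_params(mean, sd)
        assert got_shape == pytest.approx(shape, rel=1e-3)
        assert got_scale == pytest.approx(scale, rel=1e-3)

    def test_zero_sd_is_deterministic_marker(self):
        assert gamma_params(62.07, 0.0) is DETERMINISTIC

    def test_nonpositive_mean_with_sd_rejected(self):
        with pytest.raises(ValueError):
            gamma_params(0.0, 10.0)

    @settings(deadline=None, derandomize=True)
    @given(
        mean=st.floats(1e-3, 1e6, allow_nan=False),
        sd=st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_moments_recovered_algebraically(self, mean, sd):
        shape, scale = gamma_params(mean, sd)
        assert shape * scale == pytest.approx(mean, rel=1e-9)
        assert shape * scale**2 == pytest.approx(sd**2, rel=1e-9)

    def test_sampling_recovers_moments(self, rng):
        mean, sd, n = 4640.0, 1855.0, 200_000
        shape, scale = gamma_params(mean, sd)
        draws = rng.gamma(shape, scale, n)
        assert abs(draws.mean() - mean) < 3 * sd / math.sqrt(n)
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.01)
        assert (draws >= 0).all()


class TestInflation:
    SERIES = {2014: 1.00, 2018: 1.05, 2021: 1.10}

    def test_identity_and_zero(self):
        assert adjust_inflation(100, 2021, 2021, self.SERIES) == 100
        assert adjust_inflation(0, 2014, 2021, self.SERIES) == 0

    def test_direct_product(self):
        assert adjust_inflation(100, 2014, 2021, self.SERIES) == pytest.approx(110)

    def test_missing_year_named(self):
        with pytest.raises(KeyError, match="1999"):
            adjust_inflation(100, 1999, 2021, self.SERIES)

    @settings(deadline=None, derandomize=True)
    @given(cost=st.floats(0, 1e9, allow_nan=False))
    def test_transitivity(self, cost):
        via = adjust_inflation(
            adjust_inflation(cost, 2014, 2018, self.SERIES), 2018, 2021, self.SERIES
        )
        direct = adjust_inflation(cost, 2014, 2021, self.SERIES)
        assert via == pytest.approx(direct, rel=1e-12, abs=1e-12)


def test_with_overrides_revalidates(params):
    patched = params.with_overrides({"psychological": {"p_percent": 50.0}})
    assert patched.p_psychological == pytest.approx(0.5)
    with pytest.raises(ParameterValidationError):
        params.with_overrides({"psychological": {"p_percent": 150.0}})
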