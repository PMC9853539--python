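"""One-way deterministic sensitivity analysis with tornado-table output.

Each scenario perturbs one parameter group to a lower and an upper
setting while everything else stays at base; the outcome is recomputed
on the analytic expected-cost engine, so tornado ranges contain no Monte
Carlo noise.  Default scenarios: every treatment-proportion group swept
0% -> 100%, the surgery mix swept all-BCS -> all-mastectomy, the
survival table swept to 5-year / 15-year follow-up variants, and +/-20%
sweeps of the main unit-cost means.

Scenario settings are partial config documents in the same YAML dialect
as the parameter file; they are validated through the parameters module
before any outcome is computed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import pandas as pd

from . import expected
from .parameters import (
    ADVERSE_EVENT_COMPONENTS,
    INVASIVE_STAGES,
    ParameterSet,
    Stage,
    Subtype,
)

__all__ = ["ScenarioSpec", "build_default_scenarios", "run_dsa", "outcome_keys"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A one-way perturbation: config patches for the two bound settings."""

    name: str
    lower: Mapping[str, Any]
    upper: Mapping[str, Any]


def outcome_keys(params: ParameterSet) -> list[str]:
    """Valid outcome keys for :func:`run_dsa`."""
    return sorted(expected.expected_cohort_cost(params).keys())


def _all_stage_subtype(value: float) -> dict[str, dict[str, float]]:
    return {s.value: {t.value: value for t in Subtype} for s in INVASIVE_STAGES}


def _scaled_costs(params: ParameterSet, factor: float) -> dict[str, Any]:
    """Chemotherapy cost table with all means scaled by ``factor``."""
    return {
        s.value: {
            t.value: {"cost_mean": params.chemo_cost[s][t].mean * factor}
            for t in Subtype
        }
        for s in INVASIVE_STAGES
    }


def build_default_scenarios(params: ParameterSet) -> list[ScenarioSpec]:
    """The standard one-way scenario battery for the base-case model."""
    scenarios: list[ScenarioSpec] = []

    # treatment proportions swept to 0% (lower) and 100% (upper)
    scenarios.append(
        ScenarioSpec(
            "chemotherapy_proportion",
            lower={
                "chemotherapy": {
                    s.value: {t.value: {"p_percent": 0.0} for t in Subtype}
                    for s in INVASIVE_STAGES
                }
            },
            upper={
                "chemotherapy": {
                    s.value: {t.value: {"p_percent": 100.0} for t in Subtype}
                    for s in INVASIVE_STAGES
                }
            },
        )
    )
    scenarios.append(
        ScenarioSpec(
            "hormone_proportion",
            lower={"hormone_therapy": {"probability_percent": _all_stage_subtype(0.0)}},
            upper={
                "hormone_therapy": {"probability_percent": _all_stage_subtype(100.0)}
            },
        )
    )
    scenarios.append(
        ScenarioSpec(
            "radiotherapy_proportion",
            lower={
                "radiotherapy": {
                    "p_after_bcs_percent": 0.0,
                    "p_after_mastectomy_percent": 0.0,
                }
            },
            upper={
                "radiotherapy": {
                    "p_after_bcs_percent": 100.0,
                    "p_after_mastectomy_percent": 100.0,
                }
            },
        )
    )
    scenarios.append(
        ScenarioSpec(
            "ct_proportion",
            lower={
                "ct_staging": {
                    "proportion_percent": {s.value: 0.0 for s in Stage}
                }
            },
            upper={
                "ct_staging": {
                    "proportion_percent": {s.value: 100.0 for s in Stage}
                }
            },
        )
    )
    scenarios.append(
        ScenarioSpec(
            "psychological_proportion",
            lower={"psychological": {"p_percent": 0.0}},
            upper={"psychological": {"p_percent": 100.0}},
        )
    )
    scenarios.append(
        ScenarioSpec(
            "adverse_event_proportion",
            lower={
                "adverse_events": {
                    c.value: {"p_percent": 0.0} for c in ADVERSE_EVENT_COMPONENTS
                }
            },
            upper={
                "adverse_events": {
                    c.value: {"p_percent": 100.0} for c in ADVERSE_EVENT_COMPONENTS
                }
            },
        )
    )

    # surgery mix: all breast-conserving (lower) vs all mastectomy (upper)
    scenarios.append(
        ScenarioSpec(
            "surgery_mix",
            lower={
                "surgery": {
                    "p_bcs_percent": {s.value: 100.0 for s in Stage},
                    "p_mastectomy_percent": {s.value: 0.0 for s in Stage},
                }
            },
            upper={
                "surgery": {
                    "p_bcs_percent": {s.value: 0.0 for s in Stage},
                    "p_mastectomy_percent": {s.value: 100.0 for s in Stage},
                }
            },
        )
    )

    # survival horizon: 5-year (fewer deaths) vs 15-year (more deaths)
    # variants of the calibrated base table, capped at 1
    lower_surv = {s.value: params.death_prob[s] * 0.8 for s in Stage}
    upper_surv = {s.value: min(1.0, params.death_prob[s] * 1.3) for s in Stage}
    scenarios.append(
        ScenarioSpec(
            "survival_horizon",
            lower={
                "survival": {"horizon_years": 5, "death_probability": lower_surv}
            },
            upper={
                "survival": {"horizon_years": 15, "death_probability": upper_surv}
            },
        )
    )

    # +/-20% unit-cost sweeps (means only; SDs stay at base)
    def pm20(name: str, lower: Mapping, upper: Mapping) -> ScenarioSpec:
        return ScenarioSpec(f"cost_{name}_pm20", lower=lower, upper=upper)

    scenarios.append(
        pm20(
            "bcs",
            {"surgery": {"bcs": {"cost_mean": params.bcs_cost.mean * 0.8}}},
            {"surgery": {"bcs": {"cost_mean": params.bcs_cost.mean * 1.2}}},
        )
    )
    scenarios.append(
        pm20(
            "mastectomy",
            {
                "surgery": {
                    "mastectomy": {"cost_mean": params.mastectomy_cost.mean * 0.8}
                }
            },
            {
                "surgery": {
                    "mastectomy": {"cost_mean": params.mastectomy_cost.mean * 1.2}
                }
            },
        )
    )
    scenarios.append(
        pm20(
            "radiotherapy",
            {"radiotherapy": {"cost_mean": params.radiotherapy_cost.mean * 0.8}},
            {"radiotherapy": {"cost_mean": params.radiotherapy_cost.mean * 1.2}},
        )
    )
    scenarios.append(
        pm20(
            "chemotherapy",
            {"chemotherapy": _scaled_costs(params, 0.8)},
            {"chemotherapy": _scaled_costs(params, 1.2)},
        )
    )
    hf, hl = params.hormone.first_year.mean, params.hormone.later_year.mean
    scenarios.append(
        pm20(
            "hormone_therapy",
            {
                "hormone_therapy": {
                    "first_year": {"cost_mean": hf * 0.8},
                    "later_years": {"cost_mean": hl * 0.8},
                }
            },
            {
                "hormone_therapy": {
                    "first_year": {"cost_mean": hf * 1.2},
                    "later_years": {"cost_mean": hl * 1.2},
                }
            },
        )
    )
    scenarios.append(
        pm20(
            "psychological",
            {"psychological": {"cost_mean": params.psychological_cost.mean * 0.8}},
            {"psychological": {"cost_mean": params.psychological_cost.mean * 1.2}},
        )
    )
    scenarios.append(
        pm20(
            "palliative_care",
            {"palliative_care": {"cost_mean": params.palliative_cost.mean * 0.8}},
            {"palliative_care": {"cost_mean": params.palliative_cost.mean * 1.2}},
        )
    )
    return scenarios


def run_dsa(
    params: ParameterSet,
    scenarios: list[ScenarioSpec] | None = None,
    outcome: str = "per_incident_invasive",
) -> pd.DataFrame:
    """Evaluate every scenario analytically and build the tornado table.

    Returns a DataFrame with columns ``scenario``, ``lower_outcome``,
    ``upper_outcome``, ``base_outcome``, ``range``, sorted descending by
    range (ties alphabetical by scenario name).  All scenario settings
    are validated before any outcome is computed.
    """
    if scenarios is None:
        scenarios = build_default_scenarios(params)
    base_all = expected.expected_cohort_cost(params)
    if outcome not in base_all:
        raise KeyError(
            f"unknown outcome {outcome!r}; valid keys: {sorted(base_all)}"
        )
    # validate everything up front (with_overrides re-runs full validation)
    settings = [
        (spec.name, params.with_overrides(spec.lower), params.with_overrides(spec.upper))
        for spec in scenarios
    ]
    base = base_all[outcome]
    rows = []
    for name, p_lo, p_hi in settings:
        lo = expected.expected_cohort_cost(p_lo)[outcome]
        hi = expected.expected_cohort_cost(p_hi)[outcome]
        rows.append(
            {
                "scenario": name,
                "lower_outcome": lo,
                "upper_outcome": hi,
                "base_outcome": base,
                "range": abs(hi - lo),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["scenario", "lower_outcome", "upper_outcome", "base_outcome", "range"],
    )
    if not table.empty:
        table = table.sort_values(
            ["range", "scenario"], ascending=[False, True]
        ).reset_index(drop=True)
    return table
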