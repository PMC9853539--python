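"""Closed-form expected-cost engine.

Because the decision tree is a finite probability tree with independent
chance nodes and linear payoffs, every per-patient expectation has an
exact closed form: the probability of receiving a component times its
mean unit cost, summed over receptor subtypes weighted by the stage's
subtype mix.  This engine is the noise-free oracle for the Monte Carlo
simulator and the outcome function for deterministic sensitivity
analysis.

Phase-of-care attribution follows the claims-data convention used for
external validation: the *initial* phase covers the first-year treatment
bundle of women who do not die of breast cancer; the *intermediate*
phase covers later-year endocrine cycles and annual surveillance of
survivors; the *terminal* phase covers decedents, who receive the
first-year bundle plus palliative care but no later-year cycles and no
surveillance.  With stage death probability ``d`` the exact identity

    (1 - d) * (initial + intermediate) + d * terminal == stage cost

holds by construction (phase expectations are conditional on the
survival outcome; an impossible conditioning set has expectation 0).
Accordingly the ``hormone_therapy`` component expectation carries the
survival weight on its later-year cycles, and ``surveillance`` is
survival-weighted too, so the stage cost is exactly the sum of the
component expectations plus death-weighted palliative care.
"""
from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .parameters import (
    ADVERSE_EVENT_COMPONENTS,
    INVASIVE_STAGES,
    Component,
    ParameterSet,
    Stage,
    Subtype,
)

__all__ = [
    "PHASES",
    "expected_component_cost",
    "expected_stage_cost",
    "expected_phase_cost",
    "expected_cohort_cost",
    "expectation_table",
]

PHASES = ("initial", "intermediate", "terminal")

#: Aggregate pseudo-components accepted by :func:`expected_component_cost`.
SURGERY = "surgery"
ADVERSE_EVENTS = "adverse_events"


def _subtype_weighted(
    params: ParameterSet, stage: Stage, table: dict[Stage, dict[Subtype, float]]
) -> float:
    """Stage-level probability of a subtype-conditional treatment."""
    if not stage.is_invasive:
        return 0.0
    return sum(
        params.subtype_fractions[stage][t] * table[stage][t] for t in Subtype
    )


def chemo_probability(params: ParameterSet, stage: Stage) -> float:
    """Total probability of receiving any chemotherapy at a stage."""
    return _subtype_weighted(params, stage, params.p_chemo)


def hormone_probability(params: ParameterSet, stage: Stage) -> float:
    """Total probability of receiving endocrine therapy at a stage."""
    return _subtype_weighted(params, stage, params.p_hormone)


def _hormone_first_year(params: ParameterSet, stage: Stage) -> float:
    return hormone_probability(params, stage) * params.hormone.first_year.mean


def _hormone_later_years(params: ParameterSet, stage: Stage) -> float:
    """Expected later-year endocrine cost, conditional on surviving."""
    n_later = params.hormone.duration_years - 1
    return hormone_probability(params, stage) * n_later * params.hormone.later_year.mean


def _surveillance(params: ParameterSet, stage: Stage) -> float:
    """Expected surveillance cost, conditional on surviving (invasive only)."""
    if not stage.is_invasive:
        return 0.0
    n_later = params.hormone.duration_years - 1
    return n_later * params.surveillance_annual_cost


def expected_component_cost(
    stage: Stage, component: Component | str, params: ParameterSet
) -> float:
    """Exact expected per-patient cost of one care component at a stage.

    ``component`` accepts a :class:`Component` member or its string
    value, plus the aggregates ``"surgery"`` (BCS + mastectomy) and
    ``"adverse_events"`` (all chemotherapy-induced items).  Later-year
    endocrine cycles and surveillance carry the stage's survival weight
    (decedents never reach them), so stage cost decomposes exactly over
    components.
    """
    d = params.death_prob[stage]
    key = component.value if isinstance(component, Component) else str(component)

    if key == SURGERY:
        return (
            params.p_bcs[stage] * params.bcs_cost.mean
            + params.p_mastectomy[stage] * params.mastectomy_cost.mean
        )
    if key == ADVERSE_EVENTS:
        return sum(
            expected_component_cost(stage, c, params)
            for c in ADVERSE_EVENT_COMPONENTS
        )
    try:
        comp = Component(key)
    except ValueError:
        valid = [c.value for c in Component] + [SURGERY, ADVERSE_EVENTS]
        raise ValueError(
            f"unknown component {component!r}; expected one of {valid}"
        ) from None

    if comp is Component.DIAGNOSTICS:
        return params.diagnostics_cost
    if comp is Component.CT_STAGING:
        return params.ct_proportion[stage] * params.ct_cost.mean
    if comp is Component.BCS:
        return params.p_bcs[stage] * params.bcs_cost.mean
    if comp is Component.MASTECTOMY:
        return params.p_mastectomy[stage] * params.mastectomy_cost.mean
    if comp is Component.RADIOTHERAPY:
        p = (
            params.p_bcs[stage] * params.p_radio_after_bcs
            + params.p_mastectomy[stage] * params.p_radio_after_mastectomy
        )
        return p * params.radiotherapy_cost.mean
    if comp is Component.HORMONE_THERAPY:
        return _hormone_first_year(params, stage) + (1.0 - d) * _hormone_later_years(
            params, stage
        )
    if comp is Component.CHEMOTHERAPY:
        if not stage.is_invasive:
            return 0.0
        return sum(
            params.subtype_fractions[stage][t]
            * params.p_chemo[stage][t]
            * params.chemo_cost[stage][t].mean
            for t in Subtype
        )
    if comp in params.adverse_events:
        item = params.adverse_events[comp]
        if not item.applies_to(stage):
            return 0.0
        return chemo_probability(params, stage) * item.probability * item.cost.mean
    if comp is Component.PALLIATIVE_CARE:
        return d * params.palliative_cost.mean
    if comp is Component.PSYCHOLOGICAL:
        return params.p_psychological * params.psychological_cost.mean
    if comp is Component.TRANSPORT:
        return params.p_transport * params.transport_cost.mean
    if comp is Component.SURVEILLANCE:
        return (1.0 - d) * _surveillance(params, stage)
    raise ValueError(f"component {comp} has no cost rule")  # pragma: no cover


def _first_year_bundle(params: ParameterSet, stage: Stage) -> float:
    """Expected first-year treatment cost (shared by survivors and decedents)."""
    return (
        expected_component_cost(stage, Component.DIAGNOSTICS, params)
        + expected_component_cost(stage, Component.CT_STAGING, params)
        + expected_component_cost(stage, SURGERY, params)
        + expected_component_cost(stage, Component.RADIOTHERAPY, params)
        + _hormone_first_year(params, stage)
        + expected_component_cost(stage, Component.CHEMOTHERAPY, params)
        + expected_component_cost(stage, ADVERSE_EVENTS, params)
        + expected_component_cost(stage, Component.PSYCHOLOGICAL, params)
        + expected_component_cost(stage, Component.TRANSPORT, params)
    )


def expected_phase_cost(stage: Stage, phase: str, params: ParameterSet) -> float:
    """Expected per-patient cost of a phase, conditional on the phase's
    survival outcome (0 for an empty conditioning set)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    d = params.death_prob[stage]
    if phase == "initial":
        if d >= 1.0:
            return 0.0
        return _first_year_bundle(params, stage)
    if phase == "intermediate":
        if d >= 1.0:
            return 0.0
        return _hormone_later_years(params, stage) + _surveillance(params, stage)
    # terminal
    if d <= 0.0:
        return 0.0
    return _first_year_bundle(params, stage) + params.palliative_cost.mean


def expected_stage_cost(stage: Stage, params: ParameterSet) -> float:
    """Exact expected per-patient cost of a stage over the model horizon."""
    d = params.death_prob[stage]
    return (
        _first_year_bundle(params, stage)
        + (1.0 - d)
        * (_hormone_later_years(params, stage) + _surveillance(params, stage))
        + d * params.palliative_cost.mean
    )


def expected_cohort_cost(params: ParameterSet) -> dict[str, float]:
    """Incidence-weighted expected costs for the full incident cohort.

    Returns per-stage means, the per-incident-case mean over invasive
    stages (the headline convention, DCIS reported separately) and over
    all stages, survivor/decedent-weighted phase means across invasive
    stages, and national totals (mean x incident cases).  Stages with
    zero incidence simply drop out of the weights.
    """
    out: dict[str, float] = {}
    for s in Stage:
        out[f"stage_{s.value}_mean"] = expected_stage_cost(s, params)
        out[f"stage_{s.value}_total"] = (
            out[f"stage_{s.value}_mean"] * params.incidence[s]
        )

    def weighted(stages: Iterable[Stage]) -> float:
        pairs = [(params.incidence[s], expected_stage_cost(s, params)) for s in stages]
        n = sum(w for w, _ in pairs)
        return sum(w * v for w, v in pairs) / n if n else 0.0

    out["per_incident_invasive"] = weighted(INVASIVE_STAGES)
    out["per_incident_all"] = weighted(Stage)
    out["national_total_invasive"] = sum(
        out[f"stage_{s.value}_total"] for s in INVASIVE_STAGES
    )
    out["national_total_all"] = sum(out[f"stage_{s.value}_total"] for s in Stage)

    for phase in PHASES:
        num = den = 0.0
        for s in INVASIVE_STAGES:
            d = params.death_prob[s]
            w = params.incidence[s] * (d if phase == "terminal" else 1.0 - d)
            num += w * expected_phase_cost(s, phase, params)
            den += w
        out[f"phase_{phase}_mean"] = num / den if den else 0.0
    return out


def expectation_table(params: ParameterSet) -> pd.DataFrame:
    """Long-format table of component expectations per stage.

    Columns: ``stage``, ``component``, ``phase``, ``expected_eur`` —
    suitable for diffing against simulation aggregates.
    """
    phase_of = {
        Component.HORMONE_THERAPY: "mixed",  # first year initial, later intermediate
        Component.SURVEILLANCE: "intermediate",
        Component.PALLIATIVE_CARE: "terminal",
    }
    rows = []
    for s in Stage:
        for comp in Component:
            if comp in (Component.BCS, Component.MASTECTOMY):
                continue
            rows.append(
                {
                    "stage": s.value,
                    "component": comp.value,
                    "phase": phase_of.get(comp, "initial"),
                    "expected_eur": expected_component_cost(s, comp, params),
                }
            )
        rows.append(
            {
                "stage": s.value,
                "component": SURGERY,
                "phase": "initial",
                "expected_eur": expected_component_cost(s, SURGERY, params),
            }
        )
        rows.append(
            {
                "stage": s.value,
                "component": "total",
                "phase": "all",
                "expected_eur": expected_stage_cost(s, params),
            }
        )
    return pd.DataFrame(rows)
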