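"""Patient-level Monte Carlo cost simulation.

For every treatment a patient actually receives, a realized unit cost is
drawn from the moment-matched gamma distribution of that component
(fixed tariffs with SD 0 are returned exactly); draws are independent
across components and patients.  Endocrine therapy draws one first-year
cycle plus ``duration_years - 1`` independent later-year cycles, the
latter only for patients who do not die of breast cancer.  Costs are
attributed to phases of care: survivors accumulate the first-year bundle
in the initial phase and later-year endocrine cycles plus surveillance
in the intermediate phase; decedents accumulate everything, including
one palliative-care draw, in the terminal phase.

The draw order is documented and fixed — stage-major, component-major in
resource-table order, patient-minor; gamma draws are made only for
patients whose flag is set — so a fixed seed reproduces bit-identical
records.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Patient, TREATMENT_COLUMNS
from .parameters import (
    ADVERSE_EVENT_COMPONENTS,
    DETERMINISTIC,
    Component,
    ParameterSet,
    Stage,
    Subtype,
    UnitCost,
    gamma_params,
)

__all__ = [
    "PatientCostRecord",
    "draw_unit_cost",
    "simulate_patient_costs",
    "simulate_cohort_costs",
    "records_long",
]

#: Realized-cost columns of a record frame (component order + endocrine split).
COST_COLUMNS: tuple[str, ...] = tuple(c.value for c in Component)


@dataclass
class PatientCostRecord:
    """Realized per-patient costs with phase attribution."""

    patient_id: int
    stage: Stage
    dies_of_bc: bool
    component_costs: dict[Component, float]
    total: float
    initial: float
    intermediate: float
    terminal: float


def _sample(cost: UnitCost, rng: np.random.Generator, size: int) -> np.ndarray:
    """Vector of realized unit costs; degenerate SD returns the mean."""
    if size == 0:
        return np.empty(0)
    gp = gamma_params(cost.mean, cost.sd) if cost.mean > 0 or cost.sd > 0 else None
    if gp is None:
        return np.zeros(size)
    if gp is DETERMINISTIC:
        return np.full(size, cost.mean)
    shape, scale = gp
    return rng.gamma(shape, scale, size)


def _unit_cost_for(
    component: Component,
    params: ParameterSet,
    stage: Stage | None = None,
    subtype: Subtype | None = None,
) -> UnitCost:
    if component is Component.DIAGNOSTICS:
        return UnitCost(params.diagnostics_cost, 0.0)
    if component is Component.CT_STAGING:
        return params.ct_cost
    if component is Component.BCS:
        return params.bcs_cost
    if component is Component.MASTECTOMY:
        return params.mastectomy_cost
    if component is Component.RADIOTHERAPY:
        return params.radiotherapy_cost
    if component is Component.HORMONE_THERAPY:
        return params.hormone.first_year
    if component is Component.CHEMOTHERAPY:
        if stage is None or subtype is None:
            raise ValueError("chemotherapy cost requires stage and subtype")
        return params.chemo_cost[stage][subtype]
    if component in params.adverse_events:
        return params.adverse_events[component].cost
    if component is Component.PALLIATIVE_CARE:
        return params.palliative_cost
    if component is Component.PSYCHOLOGICAL:
        return params.psychological_cost
    if component is Component.TRANSPORT:
        return params.transport_cost
    if component is Component.SURVEILLANCE:
        n_later = params.hormone.duration_years - 1
        return UnitCost(n_later * params.surveillance_annual_cost, 0.0)
    raise ValueError(f"component {component} has no unit cost")  # pragma: no cover


def draw_unit_cost(
    component: Component,
    params: ParameterSet,
    rng: np.random.Generator,
    stage: Stage | None = None,
    subtype: Subtype | None = None,
) -> float:
    """One realized unit cost for a component (gamma draw, or the exact
    mean for a fixed tariff)."""
    return float(_sample(_unit_cost_for(component, params, stage, subtype), rng, 1)[0])


def _simulate_frame(
    patients: pd.DataFrame, params: ParameterSet, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorized cost realization for a cohort frame."""
    n_total = len(patients)
    costs = {col: np.zeros(n_total) for col in COST_COLUMNS}
    hormone_later = np.zeros(n_total)
    n_later = params.hormone.duration_years - 1

    for stage in Stage:
        mask = (patients["stage"] == stage.value).to_numpy()
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        block = patients.iloc[idx]
        dies = block["dies_of_bc"].to_numpy()
        subtype = block["subtype"].to_numpy()

        def draw_into(comp: Component, flag: np.ndarray, cost: UnitCost) -> None:
            take = np.flatnonzero(flag)
            if take.size:
                costs[comp.value][idx[take]] += _sample(cost, rng, take.size)

        draw_into(
            Component.DIAGNOSTICS,
            block[Component.DIAGNOSTICS.value].to_numpy(),
            UnitCost(params.diagnostics_cost, 0.0),
        )
        draw_into(
            Component.CT_STAGING,
            block[Component.CT_STAGING.value].to_numpy(),
            params.ct_cost,
        )
        draw_into(Component.BCS, block[Component.BCS.value].to_numpy(), params.bcs_cost)
        draw_into(
            Component.MASTECTOMY,
            block[Component.MASTECTOMY.value].to_numpy(),
            params.mastectomy_cost,
        )
        draw_into(
            Component.RADIOTHERAPY,
            block[Component.RADIOTHERAPY.value].to_numpy(),
            params.radiotherapy_cost,
        )
        # endocrine therapy: first-year cycle for all treated, later-year
        # cycles (independent draws) only for treated survivors
        ht = block[Component.HORMONE_THERAPY.value].to_numpy()
        draw_into(Component.HORMONE_THERAPY, ht, params.hormone.first_year)
        later_take = np.flatnonzero(ht & ~dies)
        if later_take.size and n_later > 0:
            draws = np.empty((n_later, later_take.size))
            for cycle in range(n_later):
                draws[cycle] = _sample(
                    params.hormone.later_year, rng, later_take.size
                )
            later_sum = draws.sum(axis=0)
            hormone_later[idx[later_take]] += later_sum
            costs[Component.HORMONE_THERAPY.value][idx[later_take]] += later_sum
        # chemotherapy, cost resolved per subtype (HR+, HER2+, TN order)
        chemo = block[Component.CHEMOTHERAPY.value].to_numpy()
        if stage.is_invasive:
            for sub in Subtype:
                draw_into(
                    Component.CHEMOTHERAPY,
                    chemo & (subtype == sub.value),
                    params.chemo_cost[stage][sub],
                )
        for comp in ADVERSE_EVENT_COMPONENTS:
            draw_into(
                comp, block[comp.value].to_numpy(), params.adverse_events[comp].cost
            )
        draw_into(
            Component.PALLIATIVE_CARE,
            block[Component.PALLIATIVE_CARE.value].to_numpy(),
            params.palliative_cost,
        )
        draw_into(
            Component.PSYCHOLOGICAL,
            block[Component.PSYCHOLOGICAL.value].to_numpy(),
            params.psychological_cost,
        )
        draw_into(
            Component.TRANSPORT,
            block[Component.TRANSPORT.value].to_numpy(),
            params.transport_cost,
        )
        # annual surveillance for surviving invasive patients (fixed tariff)
        if stage.is_invasive and n_later > 0:
            surv_take = np.flatnonzero(~dies)
            costs[Component.SURVEILLANCE.value][idx[surv_take]] += (
                n_later * params.surveillance_annual_cost
            )

    records = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "stage": patients["stage"].to_numpy(),
            "dies_of_bc": patients["dies_of_bc"].to_numpy(),
            **costs,
        }
    )
    total = sum(costs[col] for col in COST_COLUMNS)
    dies_all = patients["dies_of_bc"].to_numpy()
    intermediate = np.where(
        dies_all, 0.0, hormone_later + costs[Component.SURVEILLANCE.value]
    )
    records["total"] = total
    records["terminal"] = np.where(dies_all, total, 0.0)
    records["intermediate"] = intermediate
    records["initial"] = np.where(dies_all, 0.0, total - intermediate)
    return records


def simulate_cohort_costs(
    cohort: Cohort, params: ParameterSet, seed: int | None = None
) -> pd.DataFrame:
    """Realized cost records for a whole cohort, one row per patient.

    ``seed`` seeds the cost-draw stream; it defaults to ``cohort.seed + 1``
    so cohort generation and cost realization use distinct streams.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if seed is None:
        seed = cohort.seed + 1
    rng = np.random.default_rng(seed)
    return _simulate_frame(cohort.patients, params, rng)


def simulate_patient_costs(
    patient: Patient, params: ParameterSet, rng: np.random.Generator
) -> PatientCostRecord:
    """Realized costs of one patient with assigned treatments."""
    if not patient.treatments:
        raise ValueError(f"patient {patient.id} has no assigned treatments")
    row = {
        "patient_id": patient.id,
        "stage": patient.stage.value,
        "subtype": patient.subtype.value if patient.subtype else "",
        "dies_of_bc": patient.dies_of_bc,
    }
    row.update({c: patient.treatments[Component(c)] for c in TREATMENT_COLUMNS})
    rec = _simulate_frame(pd.DataFrame([row]), params, rng).iloc[0]
    return PatientCostRecord(
        patient_id=patient.id,
        stage=patient.stage,
        dies_of_bc=patient.dies_of_bc,
        component_costs={Component(c): float(rec[c]) for c in COST_COLUMNS},
        total=float(rec["total"]),
        initial=float(rec["initial"]),
        intermediate=float(rec["intermediate"]),
        terminal=float(rec["terminal"]),
    )


def records_long(records: pd.DataFrame) -> pd.DataFrame:
    """Melt a record frame to long format (patient, component, eur > 0)."""
    long = records.melt(
        id_vars=["patient_id", "stage", "dies_of_bc"],
        value_vars=list(COST_COLUMNS),
        var_name="component",
        value_name="eur",
    )
    return long[long["eur"] > 0].reset_index(drop=True)
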