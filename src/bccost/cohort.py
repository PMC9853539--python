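"""Registry-style synthetic incident cohorts.

The model works on the annual census of newly diagnosed breast-cancer
cases, so per-stage counts are fixed quotas taken from the incidence
table (optionally scaled), never multinomially sampled.  Only patient
attributes are random: receptor subtype (drawn from the stage's
partition), the breast-cancer death indicator (Bernoulli with the
stage-specific probability), and the realized treatment flags of the
decision tree.

All draws come from one shared numpy Generator with a documented order —
stage-major (DCIS, I, II, III, IV), component-major within stage (the
resource-table order of :class:`~bccost.parameters.Component`),
patient-minor — so that a fixed (seed, parameter set) pair reproduces a
bit-identical cohort.  Uniform draws are consumed for every patient of a
stage even where a flag is structurally impossible (e.g. chemotherapy
for DCIS), which keeps the stream alignment independent of parameter
values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ADVERSE_EVENT_COMPONENTS,
    Component,
    ParameterSet,
    Stage,
    Subtype,
)

__all__ = ["Patient", "Cohort", "generate_cohort", "assign_treatments",
           "TREATMENT_COLUMNS"]

#: Boolean treatment-flag columns of a cohort frame, in draw order.
TREATMENT_COLUMNS: tuple[str, ...] = (
    Component.DIAGNOSTICS.value,
    Component.CT_STAGING.value,
    Component.BCS.value,
    Component.MASTECTOMY.value,
    Component.RADIOTHERAPY.value,
    Component.HORMONE_THERAPY.value,
    Component.CHEMOTHERAPY.value,
    *(c.value for c in ADVERSE_EVENT_COMPONENTS),
    Component.PALLIATIVE_CARE.value,
    Component.PSYCHOLOGICAL.value,
    Component.TRANSPORT.value,
)


@dataclass
class Patient:
    """One simulated incident case."""

    id: int
    stage: Stage
    subtype: Subtype | None  # None iff DCIS
    dies_of_bc: bool
    treatments: dict[Component, bool] = field(default_factory=dict)


@dataclass
class Cohort:
    """An ordered collection of patients with provenance metadata.

    ``patients`` is a pandas DataFrame with one row per patient:
    ``patient_id``, ``stage``, ``subtype`` (empty string for DCIS),
    ``dies_of_bc`` and one boolean column per treatment flag.
    """

    patients: pd.DataFrame
    seed: int
    scale: float
    params_digest: str

    def __len__(self) -> int:
        return len(self.patients)

    def stage_counts(self) -> dict[Stage, int]:
        counts = self.patients["stage"].value_counts()
        return {s: int(counts.get(s.value, 0)) for s in Stage}

    def to_csv(self, path: str | Path) -> None:
        self.patients.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1, scale: float = 1.0,
                 params_digest: str = "") -> "Cohort":
        df = pd.read_csv(path, keep_default_na=False)
        for col in TREATMENT_COLUMNS + ("dies_of_bc",):
            df[col] = df[col].astype(bool)
        return cls(patients=df, seed=seed, scale=scale, params_digest=params_digest)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def generate_cohort(
    params: ParameterSet, scale: float = 1.0, seed: int | None = None
) -> Cohort:
    """Generate an incident cohort with fixed per-stage counts.

    Parameters
    ----------
    params
        Validated model parameterization.
    scale
        Fraction of the incidence table to generate, in (0, 1].  Per-stage
        counts are ``round(scale * incidence)`` with half-away-from-zero
        rounding; every stage with positive incidence must keep >= 1 case.
    seed
        Seed for the shared random stream; defaults to ``params.seed``.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    if seed is None:
        seed = params.seed
    counts: dict[Stage, int] = {}
    for s in Stage:
        n = _round_half_away(scale * params.incidence[s])
        if params.incidence[s] > 0 and n < 1:
            raise ValueError(
                f"scale {scale} leaves no patients in stage {s.value}; "
                "increase the scale"
            )
        counts[s] = n

    rng = np.random.default_rng(seed)
    blocks: list[pd.DataFrame] = []
    next_id = 0
    subtype_order = list(Subtype)
    for stage in Stage:
        n = counts[stage]
        if n == 0:
            continue
        if stage.is_invasive:
            fractions = np.array(
                [params.subtype_fractions[stage][t] for t in subtype_order]
            )
            idx = rng.choice(len(subtype_order), size=n, p=fractions)
            subtype = np.array([subtype_order[i].value for i in idx])
        else:
            subtype = np.full(n, "", dtype=object)
        dies = rng.random(n) < params.death_prob[stage]
        block = pd.DataFrame(
            {
                "patient_id": np.arange(next_id, next_id + n),
                "stage": stage.value,
                "subtype": subtype,
                "dies_of_bc": dies,
            }
        )
        _assign_stage_block(block, stage, params, rng)
        blocks.append(block)
        next_id += n

    patients = pd.concat(blocks, ignore_index=True)
    return Cohort(
        patients=patients, seed=seed, scale=scale, params_digest=params.digest()
    )


def _assign_stage_block(
    block: pd.DataFrame, stage: Stage, params: ParameterSet, rng: np.random.Generator
) -> None:
    """Fill treatment flags for one stage block, component-major.

    One uniform is consumed per patient per chance node regardless of
    whether the node is reachable for that patient, so the draw order is
    invariant to the parameter values.
    """
    n = len(block)
    subtype = block["subtype"].to_numpy()
    dies = block["dies_of_bc"].to_numpy()

    def per_subtype(table: dict[Stage, dict[Subtype, float]]) -> np.ndarray:
        if not stage.is_invasive:
            return np.zeros(n)
        probs = {t.value: table[stage][t] for t in Subtype}
        return np.array([probs[s] for s in subtype])

    block[Component.DIAGNOSTICS.value] = True
    block[Component.CT_STAGING.value] = rng.random(n) < params.ct_proportion[stage]
    bcs = rng.random(n) < params.p_bcs[stage]
    block[Component.BCS.value] = bcs
    block[Component.MASTECTOMY.value] = ~bcs
    p_radio = np.where(
        bcs, params.p_radio_after_bcs, params.p_radio_after_mastectomy
    )
    block[Component.RADIOTHERAPY.value] = rng.random(n) < p_radio
    block[Component.HORMONE_THERAPY.value] = rng.random(n) < per_subtype(
        params.p_hormone
    )
    chemo = rng.random(n) < per_subtype(params.p_chemo)
    block[Component.CHEMOTHERAPY.value] = chemo
    for comp in ADVERSE_EVENT_COMPONENTS:
        item = params.adverse_events[comp]
        u = rng.random(n)
        flag = chemo & (u < item.probability) if item.applies_to(stage) else np.zeros(
            n, dtype=bool
        )
        block[comp.value] = flag
    block[Component.PALLIATIVE_CARE.value] = dies
    block[Component.PSYCHOLOGICAL.value] = rng.random(n) < params.p_psychological
    block[Component.TRANSPORT.value] = rng.random(n) < params.p_transport


def assign_treatments(
    patient: Patient, params: ParameterSet, rng: np.random.Generator
) -> Patient:
    """Fill the treatment flags of one patient from the decision tree.

    Uses the same chance-node routine as :func:`generate_cohort` on a
    single-row block, drawing from the supplied stream.
    """
    if patient.stage.is_invasive and patient.subtype is None:
        raise ValueError(f"invasive patient {patient.id} has no receptor subtype")
    if patient.stage.is_invasive:
        missing = [
            name
            for name, table in (
                ("hormone_therapy", params.p_hormone),
                ("chemotherapy", params.p_chemo),
            )
            if patient.subtype not in table.get(patient.stage, {})
        ]
        if missing:
            raise KeyError(
                f"no probability entry for (stage {patient.stage.value}, "
                f"{missing[0]})"
            )
    block = pd.DataFrame(
        {
            "patient_id": [patient.id],
            "stage": patient.stage.value,
            "subtype": patient.subtype.value if patient.subtype else "",
            "dies_of_bc": [patient.dies_of_bc],
        }
    )
    _assign_stage_block(block, patient.stage, params, rng)
    row = block.iloc[0]
    patient.treatments = {
        Component(col): bool(row[col]) for col in TREATMENT_COLUMNS
    }
    return patient


def patient_from_row(row: pd.Series) -> Patient:
    """Build a :class:`Patient` view from one cohort-frame row."""
    return Patient(
        id=int(row["patient_id"]),
        stage=Stage(row["stage"]),
        subtype=Subtype(row["subtype"]) if row["subtype"] else None,
        dies_of_bc=bool(row["dies_of_bc"]),
        treatments={Component(c): bool(row[c]) for c in TREATMENT_COLUMNS},
    )
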