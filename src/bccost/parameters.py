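"""Model parameterization for the stage-wise breast-cancer cost model.

Everything a single model run needs lives in one :class:`ParameterSet`:
treatment probabilities by stage and hormone-receptor subtype, unit costs
(mean and SD, 2021 EUR), stage-wise incident case counts, stage-specific
probabilities of dying of breast cancer within the model horizon, the
endocrine-therapy schedule, and an inflation index series.

Parameter sets are loaded from a human-editable YAML document whose layout
mirrors the published resource-use table: probabilities are written as
percentages (as printed) and converted to fractions on load.  The shipped
default file, ``data/default_parameters.yaml``, is the base-case
configuration of the model.
"""
from __future__ import annotations

import enum
import hashlib
import json
import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml

__all__ = [
    "Stage",
    "Subtype",
    "Component",
    "ADVERSE_EVENT_COMPONENTS",
    "INVASIVE_STAGES",
    "UnitCost",
    "HormoneSchedule",
    "AdverseEventItem",
    "DiagnosticItem",
    "ParameterSet",
    "Finding",
    "ParameterValidationError",
    "DETERMINISTIC",
    "gamma_params",
    "adjust_inflation",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "validate_parameters",
]


class Stage(str, enum.Enum):
    """Disease stage at diagnosis. DCIS is the non-invasive (stage 0) lesion."""

    DCIS = "DCIS"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]

    @property
    def is_invasive(self) -> bool:
        return self is not Stage.DCIS


_STAGE_ORDER = {s: i for i, s in enumerate(Stage)}
INVASIVE_STAGES: tuple[Stage, ...] = (Stage.I, Stage.II, Stage.III, Stage.IV)


class Subtype(str, enum.Enum):
    """Hormone-receptor subtype partition of invasive cases.

    HR_POS covers hormone-receptor-positive disease, HER2_POS covers
    HER2-positive disease (with or without HR positivity), TN is
    triple-negative.  The three are treated as mutually exclusive and
    exhaustive: per-stage fractions must sum to one.
    """

    HR_POS = "HR_POS"
    HER2_POS = "HER2_POS"
    TN = "TN"


class Component(str, enum.Enum):
    """Care components of the decision tree, in resource-table order.

    The enum order defines the documented random-draw order of the
    simulator (stage-major, component-major, patient-minor).
    """

    DIAGNOSTICS = "diagnostics"
    CT_STAGING = "ct_staging"
    BCS = "bcs"
    MASTECTOMY = "mastectomy"
    RADIOTHERAPY = "radiotherapy"
    HORMONE_THERAPY = "hormone_therapy"
    CHEMOTHERAPY = "chemotherapy"
    NEUTROPENIC_SEPSIS = "neutropenic_sepsis"
    PEGFILGRASTIM = "pegfilgrastim"
    ANTIEMETICS = "antiemetics"
    BISPHOSPHONATES = "bisphosphonates"
    LYMPH_DRAINAGE = "lymph_drainage"
    PALLIATIVE_CARE = "palliative_care"
    PSYCHOLOGICAL = "psychological_treatment"
    TRANSPORT = "transportation"
    SURVEILLANCE = "surveillance"


ADVERSE_EVENT_COMPONENTS: tuple[Component, ...] = (
    Component.NEUTROPENIC_SEPSIS,
    Component.PEGFILGRASTIM,
    Component.ANTIEMETICS,
    Component.BISPHOSPHONATES,
    Component.LYMPH_DRAINAGE,
)

#: Sentinel returned by :func:`gamma_params` for a zero-variance tariff.
DETERMINISTIC = "deterministic"


@dataclass(frozen=True)
class UnitCost:
    """A unit cost in 2021 EUR with its SD; ``sd == 0`` is a fixed tariff."""

    mean: float
    sd: float = 0.0
    reference_year: int = 2021

    @property
    def deterministic(self) -> bool:
        return self.sd == 0.0


@dataclass(frozen=True)
class HormoneSchedule:
    """Endocrine-therapy course: one first-year cycle plus later annual cycles."""

    first_year: UnitCost
    later_year: UnitCost
    duration_years: int = 5


@dataclass(frozen=True)
class AdverseEventItem:
    """A chemotherapy-induced event: probability conditional on chemotherapy."""

    probability: float
    cost: UnitCost
    stages: tuple[Stage, ...] | None = None  # None = all stages

    def applies_to(self, stage: Stage) -> bool:
        return self.stages is None or stage in self.stages


@dataclass(frozen=True)
class DiagnosticItem:
    """One fixed-tariff item of the diagnostic work-up bundle."""

    name: str
    cost: float
    per_specimen: bool = False


@dataclass(frozen=True)
class Finding:
    """A validation finding: key path into the config plus a message."""

    path: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"


class ParameterValidationError(ValueError):
    """Raised when a configuration violates the parameter invariants."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        msgs = "\n".join(str(f) for f in findings)
        super().__init__(f"invalid parameter configuration:\n{msgs}")


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated parameterization of one model run.

    All probabilities are stored as fractions in [0, 1]; the YAML config
    carries them as percentages.  Dictionaries keyed by stage cover all
    five stages unless noted; subtype-resolved tables cover invasive
    stages only (DCIS has no receptor subtype in the model).
    """

    # diagnostic work-up (fixed tariffs, applied to every diagnosed woman)
    diagnostic_items: tuple[DiagnosticItem, ...]
    specimen_count: int

    # CT staging of chest and abdomen at diagnosis
    ct_cost: UnitCost
    ct_proportion: dict[Stage, float]

    # surgery
    p_bcs: dict[Stage, float]
    p_mastectomy: dict[Stage, float]
    bcs_cost: UnitCost
    mastectomy_cost: UnitCost

    # radiotherapy after surgery, conditional on surgery type
    p_radio_after_bcs: float
    p_radio_after_mastectomy: float
    radiotherapy_cost: UnitCost

    # receptor-subtype mix of invasive stages
    subtype_fractions: dict[Stage, dict[Subtype, float]]

    # endocrine therapy
    p_hormone: dict[Stage, dict[Subtype, float]]
    hormone: HormoneSchedule

    # chemotherapy (probability and cost both stage- and subtype-specific)
    p_chemo: dict[Stage, dict[Subtype, float]]
    chemo_cost: dict[Stage, dict[Subtype, UnitCost]]

    # chemotherapy-induced events, conditional on chemotherapy
    adverse_events: dict[Component, AdverseEventItem]

    # supportive / end-of-life care
    palliative_cost: UnitCost
    p_psychological: float
    psychological_cost: UnitCost
    p_transport: float
    transport_cost: UnitCost

    # annual surveillance visit for surviving invasive patients
    surveillance_annual_cost: float

    # cohort definition
    incidence: dict[Stage, int]
    incidence_year: int

    # survival: probability of dying of breast cancer within the horizon
    death_prob: dict[Stage, float]
    horizon_years: int

    # inflation index (year -> multiplicative factor, base year = 1)
    inflation: dict[int, float]
    inflation_base_year: int

    seed: int = 20150

    # ------------------------------------------------------------------
    @property
    def diagnostics_cost(self) -> float:
        """Total cost of the diagnostic bundle (specimen items multiplied)."""
        return sum(
            it.cost * (self.specimen_count if it.per_specimen else 1)
            for it in self.diagnostic_items
        )

    @property
    def total_incidence(self) -> int:
        return sum(self.incidence.values())

    def subtypes(self, stage: Stage) -> dict[Subtype, float]:
        """Subtype partition of a stage; empty mapping for DCIS."""
        return self.subtype_fractions.get(stage, {})

    def iter_unit_costs(self) -> Iterator[tuple[str, UnitCost]]:
        """Yield every unit cost in the parameter set with a label."""
        for it in self.diagnostic_items:
            yield f"diagnostics.{it.name}", UnitCost(it.cost, 0.0)
        yield "ct_staging", self.ct_cost
        yield "bcs", self.bcs_cost
        yield "mastectomy", self.mastectomy_cost
        yield "radiotherapy", self.radiotherapy_cost
        yield "hormone_first_year", self.hormone.first_year
        yield "hormone_later_year", self.hormone.later_year
        for stage in INVASIVE_STAGES:
            for sub, uc in self.chemo_cost[stage].items():
                yield f"chemotherapy.{stage.value}.{sub.value}", uc
        for comp, item in self.adverse_events.items():
            yield comp.value, item.cost
        yield "palliative_care", self.palliative_cost
        yield "psychological_treatment", self.psychological_cost
        yield "transportation", self.transport_cost

    # ------------------------------------------------------------------
    def to_config(self) -> dict[str, Any]:
        """Serialize back to the YAML config dialect (percent form)."""
        pct = _to_percent
        cfg: dict[str, Any] = {
            "meta": {
                "price_year": self.bcs_cost.reference_year,
                "incidence_year": self.incidence_year,
                "seed": self.seed,
            },
            "incidence": {s.value: self.incidence[s] for s in Stage},
            "diagnostics": {
                "specimen_count": self.specimen_count,
                "items": [
                    {
                        "name": it.name,
                        "cost": it.cost,
                        **({"per_specimen": True} if it.per_specimen else {}),
                    }
                    for it in self.diagnostic_items
                ],
            },
            "ct_staging": {
                "cost_mean": self.ct_cost.mean,
                "cost_sd": self.ct_cost.sd,
                "proportion_percent": {
                    s.value: pct(self.ct_proportion[s]) for s in Stage
                },
            },
            "surgery": {
                "bcs": {"cost_mean": self.bcs_cost.mean, "cost_sd": self.bcs_cost.sd},
                "mastectomy": {
                    "cost_mean": self.mastectomy_cost.mean,
                    "cost_sd": self.mastectomy_cost.sd,
                },
                "p_bcs_percent": {s.value: pct(self.p_bcs[s]) for s in Stage},
                "p_mastectomy_percent": {
                    s.value: pct(self.p_mastectomy[s]) for s in Stage
                },
            },
            "radiotherapy": {
                "cost_mean": self.radiotherapy_cost.mean,
                "cost_sd": self.radiotherapy_cost.sd,
                "p_after_bcs_percent": pct(self.p_radio_after_bcs),
                "p_after_mastectomy_percent": pct(self.p_radio_after_mastectomy),
            },
            "subtype_fractions_percent": {
                s.value: {t.value: pct(f) for t, f in self.subtype_fractions[s].items()}
                for s in INVASIVE_STAGES
            },
            "hormone_therapy": {
                "first_year": {
                    "cost_mean": self.hormone.first_year.mean,
                    "cost_sd": self.hormone.first_year.sd,
                },
                "later_years": {
                    "cost_mean": self.hormone.later_year.mean,
                    "cost_sd": self.hormone.later_year.sd,
                },
                "duration_years": self.hormone.duration_years,
                "probability_percent": {
                    s.value: {t.value: pct(p) for t, p in self.p_hormone[s].items()}
                    for s in INVASIVE_STAGES
                },
            },
            "chemotherapy": {
                s.value: {
                    t.value: {
                        "p_percent": pct(self.p_chemo[s][t]),
                        "cost_mean": self.chemo_cost[s][t].mean,
                        "cost_sd": self.chemo_cost[s][t].sd,
                    }
                    for t in Subtype
                }
                for s in INVASIVE_STAGES
            },
            "adverse_events": {
                comp.value: {
                    "p_percent": pct(item.probability),
                    "cost_mean": item.cost.mean,
                    "cost_sd": item.cost.sd,
                    **(
                        {"stages": [s.value for s in item.stages]}
                        if item.stages is not None
                        else {}
                    ),
                }
                for comp, item in self.adverse_events.items()
            },
            "palliative_care": {
                "cost_mean": self.palliative_cost.mean,
                "cost_sd": self.palliative_cost.sd,
            },
            "psychological": {
                "p_percent": pct(self.p_psychological),
                "cost_mean": self.psychological_cost.mean,
                "cost_sd": self.psychological_cost.sd,
            },
            "transportation": {
                "p_percent": pct(self.p_transport),
                "cost_mean": self.transport_cost.mean,
                "cost_sd": self.transport_cost.sd,
            },
            "surveillance": {"annual_cost": self.surveillance_annual_cost},
            "survival": {
                "horizon_years": self.horizon_years,
                "death_probability": {s.value: self.death_prob[s] for s in Stage},
            },
            "inflation": {
                "base_year": self.inflation_base_year,
                "factors": dict(sorted(self.inflation.items())),
            },
        }
        return cfg

    def digest(self) -> str:
        """SHA-256 digest of the canonical config serialization."""
        blob = json.dumps(self.to_config(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        """Return a new, re-validated ParameterSet with a config patch applied.

        ``overrides`` is a partial document in the same YAML dialect;
        nested mappings are merged recursively, scalars and lists replace.
        """
        cfg = _deep_merge(self.to_config(), overrides)
        return load_parameters(cfg)


# ----------------------------------------------------------------------
# moment matching and inflation


def gamma_params(mean: float, sd: float):
    """Moment-matched gamma parameterization of a unit cost.

    Returns ``(shape, scale)`` with ``shape = (mean/sd)**2`` and
    ``scale = sd**2 / mean``, so that ``shape * scale == mean`` and
    ``shape * scale**2 == sd**2``.  A zero SD denotes a fixed tariff and
    returns the :data:`DETERMINISTIC` marker instead.
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        return DETERMINISTIC
    if mean <= 0:
        raise ValueError(
            f"gamma distribution undefined for mean {mean} with sd {sd} > 0"
        )
    return (mean / sd) ** 2, sd * sd / mean


def adjust_inflation(
    cost: float, from_year: int, to_year: int, series: Mapping[int, float]
) -> float:
    """Re-express ``cost`` from ``from_year`` prices in ``to_year`` prices.

    Exact multiplication by the ratio of index factors; no rounding.
    """
    for year in (from_year, to_year):
        if year not in series:
            raise KeyError(f"year {year} missing from inflation series")
    return cost * series[to_year] / series[from_year]


# ----------------------------------------------------------------------
# loading / validation


def _to_percent(frac: float) -> float:
    # round to kill float fuzz from the /100 conversion so that
    # load -> serialize -> load round-trips bit-identically
    return round(frac * 100.0, 9)


def _deep_merge(base: dict, patch: Mapping) -> dict:
    out = dict(base)
    for key, value in patch.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _frac(cfg: Mapping, *path: str) -> float:
    node: Any = cfg
    for key in path:
        try:
            node = node[key]
        except (KeyError, TypeError):
            raise ParameterValidationError(
                [Finding(".".join(path), "missing configuration key")]
            ) from None
    if not isinstance(node, (int, float)):
        raise ParameterValidationError(
            [Finding(".".join(path), f"expected a number, got {node!r}")]
        )
    return float(node) / 100.0


def _unit_cost(node: Mapping, year: int) -> UnitCost:
    return UnitCost(
        mean=float(node["cost_mean"]), sd=float(node.get("cost_sd", 0.0)),
        reference_year=year,
    )


def default_parameters() -> ParameterSet:
    """Load the shipped base-case configuration."""
    ref = resources.files("bccost.data").joinpath("default_parameters.yaml")
    with ref.open("r") as fh:
        return load_parameters(yaml.safe_load(fh))


def load_parameters(source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Load and validate a parameter configuration.

    ``source`` may be a mapping (already-parsed document) or a path to a
    YAML file.  Percent-valued keys are converted to fractions.  All
    invariant violations are collected and raised together.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"parameter config not found: {path}")
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ParameterValidationError(
            [Finding("<root>", "config document must be a mapping")]
        )

    meta = cfg.get("meta", {})
    year = int(meta.get("price_year", 2021))

    try:
        diag_cfg = cfg["diagnostics"]
        items = tuple(
            DiagnosticItem(
                name=str(it["name"]),
                cost=float(it["cost"]),
                per_specimen=bool(it.get("per_specimen", False)),
            )
            for it in diag_cfg["items"]
        )
        ct_cfg = cfg["ct_staging"]
        surg = cfg["surgery"]
        radio = cfg["radiotherapy"]
        hormone_cfg = cfg["hormone_therapy"]
        chemo_cfg = cfg["chemotherapy"]
        ae_cfg = cfg["adverse_events"]
        surv_cfg = cfg["survival"]
        infl_cfg = cfg.get("inflation", {"base_year": year, "factors": {year: 1.0}})

        params = ParameterSet(
            diagnostic_items=items,
            specimen_count=int(diag_cfg.get("specimen_count", 3)),
            ct_cost=_unit_cost(ct_cfg, year),
            ct_proportion={
                s: _frac(ct_cfg["proportion_percent"], s.value) for s in Stage
            },
            p_bcs={s: _frac(surg["p_bcs_percent"], s.value) for s in Stage},
            p_mastectomy={
                s: _frac(surg["p_mastectomy_percent"], s.value) for s in Stage
            },
            bcs_cost=_unit_cost(surg["bcs"], year),
            mastectomy_cost=_unit_cost(surg["mastectomy"], year),
            p_radio_after_bcs=float(radio["p_after_bcs_percent"]) / 100.0,
            p_radio_after_mastectomy=float(radio["p_after_mastectomy_percent"]) / 100.0,
            radiotherapy_cost=_unit_cost(radio, year),
            subtype_fractions={
                s: {
                    t: _frac(cfg["subtype_fractions_percent"], s.value, t.value)
                    for t in Subtype
                }
                for s in INVASIVE_STAGES
            },
            p_hormone={
                s: {
                    t: _frac(hormone_cfg["probability_percent"], s.value, t.value)
                    for t in Subtype
                }
                for s in INVASIVE_STAGES
            },
            hormone=HormoneSchedule(
                first_year=_unit_cost(hormone_cfg["first_year"], year),
                later_year=_unit_cost(hormone_cfg["later_years"], year),
                duration_years=int(hormone_cfg.get("duration_years", 5)),
            ),
            p_chemo={
                s: {
                    t: float(chemo_cfg[s.value][t.value]["p_percent"]) / 100.0
                    for t in Subtype
                }
                for s in INVASIVE_STAGES
            },
            chemo_cost={
                s: {t: _unit_cost(chemo_cfg[s.value][t.value], year) for t in Subtype}
                for s in INVASIVE_STAGES
            },
            adverse_events={
                Component(name): AdverseEventItem(
                    probability=float(node["p_percent"]) / 100.0,
                    cost=_unit_cost(node, year),
                    stages=(
                        tuple(Stage(s) for s in node["stages"])
                        if "stages" in node
                        else None
                    ),
                )
                for name, node in ae_cfg.items()
            },
            palliative_cost=_unit_cost(cfg["palliative_care"], year),
            p_psychological=float(cfg["psychological"]["p_percent"]) / 100.0,
            psychological_cost=_unit_cost(cfg["psychological"], year),
            p_transport=float(cfg["transportation"]["p_percent"]) / 100.0,
            transport_cost=_unit_cost(cfg["transportation"], year),
            surveillance_annual_cost=float(cfg["surveillance"]["annual_cost"]),
            incidence={s: int(cfg["incidence"][s.value]) for s in Stage},
            incidence_year=int(meta.get("incidence_year", 2015)),
            death_prob={
                s: float(surv_cfg["death_probability"][s.value]) for s in Stage
            },
            horizon_years=int(surv_cfg.get("horizon_years", 10)),
            inflation={int(y): float(f) for y, f in infl_cfg["factors"].items()},
            inflation_base_year=int(infl_cfg["base_year"]),
            seed=int(meta.get("seed", 20150)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ParameterValidationError):
            raise
        raise ParameterValidationError(
            [Finding("<schema>", f"malformed configuration: {exc!r}")]
        ) from exc

    findings = validate_parameters(params)
    errors = [f for f in findings if f.severity == "error"]
    for f in findings:
        if f.severity == "warning":
            warnings.warn(str(f), stacklevel=2)
    if errors:
        raise ParameterValidationError(errors)
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back out as a YAML config document."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_config(), fh, sort_keys=False)


def validate_parameters(params: ParameterSet) -> list[Finding]:
    """Check every parameter invariant; return all findings (no exceptions)."""
    findings: list[Finding] = []
    tol = 1e-9

    def check_prob(value: float, path: str) -> None:
        if not (0.0 <= value <= 1.0):
            findings.append(Finding(path, f"probability {value} outside [0, 1]"))

    def check_cost(uc: UnitCost, path: str) -> None:
        if uc.mean < 0:
            findings.append(Finding(path, f"mean cost {uc.mean} is negative"))
        if uc.sd < 0:
            findings.append(Finding(path, f"cost SD {uc.sd} is negative"))
        if uc.mean <= 0 and uc.sd > 0:
            findings.append(
                Finding(path, "gamma cost undefined: non-positive mean with sd > 0")
            )

    for it in params.diagnostic_items:
        if it.cost < 0:
            findings.append(
                Finding(f"diagnostics.items.{it.name}", "negative tariff")
            )
    if params.specimen_count < 1:
        findings.append(
            Finding("diagnostics.specimen_count", "must be a positive integer")
        )

    for s in Stage:
        check_prob(params.ct_proportion[s], f"ct_staging.proportion.{s.value}")
        check_prob(params.p_bcs[s], f"surgery.p_bcs.{s.value}")
        check_prob(params.p_mastectomy[s], f"surgery.p_mastectomy.{s.value}")
        if abs(params.p_bcs[s] + params.p_mastectomy[s] - 1.0) > tol:
            findings.append(
                Finding(
                    f"surgery.{s.value}",
                    "P(BCS) + P(mastectomy) must equal 1, got "
                    f"{params.p_bcs[s] + params.p_mastectomy[s]:.6f}",
                )
            )
        check_prob(params.death_prob[s], f"survival.death_probability.{s.value}")
        if params.incidence[s] < 0:
            findings.append(
                Finding(f"incidence.{s.value}", "case count must be non-negative")
            )

    check_prob(params.p_radio_after_bcs, "radiotherapy.p_after_bcs")
    check_prob(params.p_radio_after_mastectomy, "radiotherapy.p_after_mastectomy")
    check_prob(params.p_psychological, "psychological.p")
    check_prob(params.p_transport, "transportation.p")

    for s in INVASIVE_STAGES:
        total = sum(params.subtype_fractions[s].values())
        if abs(total - 1.0) > tol:
            findings.append(
                Finding(
                    f"subtype_fractions.{s.value}",
                    f"subtype fractions sum to {total:.6f}, expected 1.0",
                )
            )
        for t in Subtype:
            check_prob(
                params.subtype_fractions[s][t],
                f"subtype_fractions.{s.value}.{t.value}",
            )
            check_prob(params.p_hormone[s][t], f"hormone.p.{s.value}.{t.value}")
            check_prob(params.p_chemo[s][t], f"chemotherapy.p.{s.value}.{t.value}")
            check_cost(
                params.chemo_cost[s][t], f"chemotherapy.cost.{s.value}.{t.value}"
            )

    for comp, item in params.adverse_events.items():
        check_prob(item.probability, f"adverse_events.{comp.value}.p")
        check_cost(item.cost, f"adverse_events.{comp.value}.cost")

    for name, uc in (
        ("ct_staging", params.ct_cost),
        ("surgery.bcs", params.bcs_cost),
        ("surgery.mastectomy", params.mastectomy_cost),
        ("radiotherapy", params.radiotherapy_cost),
        ("hormone.first_year", params.hormone.first_year),
        ("hormone.later_years", params.hormone.later_year),
        ("palliative_care", params.palliative_cost),
        ("psychological", params.psychological_cost),
        ("transportation", params.transport_cost),
    ):
        check_cost(uc, name)
    if params.surveillance_annual_cost < 0:
        findings.append(Finding("surveillance.annual_cost", "negative cost"))

    # survival structure
    if params.death_prob[Stage.DCIS] > 0:
        findings.append(
            Finding(
                "survival.death_probability.DCIS",
                "base case assumes no breast-cancer deaths among DCIS",
                severity="warning",
            )
        )
    probs = [params.death_prob[s] for s in INVASIVE_STAGES]
    if any(b < a - tol for a, b in zip(probs, probs[1:])):
        findings.append(
            Finding(
                "survival.death_probability",
                "death probability must be non-decreasing with stage",
            )
        )
    if params.horizon_years < 1:
        findings.append(Finding("survival.horizon_years", "must be >= 1"))

    if params.hormone.duration_years < 1:
        findings.append(Finding("hormone_therapy.duration_years", "must be >= 1"))
    elif not (2 <= params.hormone.duration_years <= 5):
        findings.append(
            Finding(
                "hormone_therapy.duration_years",
                "endocrine therapy is usually given for 2-5 years",
                severity="warning",
            )
        )

    for y, f in params.inflation.items():
        if f <= 0:
            findings.append(Finding(f"inflation.factors.{y}", "factor must be > 0"))
    base = params.inflation.get(params.inflation_base_year)
    if base is None:
        findings.append(
            Finding("inflation.base_year", "base year missing from factor table")
        )
    elif abs(base - 1.0) > tol:
        findings.append(
            Finding("inflation.base_year", f"base-year factor must be 1, got {base}")
        )

    return findings
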