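"""Aggregation and reporting: stage/phase summaries, percent increases,
national totals, cost-driver shares, and external benchmark comparison.

Summaries report the sample mean, sample SD, a normal-approximation 95%
confidence interval of the mean (z = 1.96), and the total (mean x n).
Euro amounts are kept unrounded internally; rounding is left to the
presentation layer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ADVERSE_EVENT_COMPONENTS, Component, Stage

__all__ = [
    "StageSummary",
    "BenchmarkComparison",
    "Z_95",
    "normal_ci",
    "summarize",
    "phase_records",
    "percent_increase_vs_reference",
    "national_total",
    "component_shares",
    "compare_to_benchmark",
    "load_benchmarks",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96


def normal_ci(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI of a mean from summary statistics."""
    half = Z_95 * sd / np.sqrt(n)
    return mean - half, mean + half


@dataclass(frozen=True)
class StageSummary:
    """Per-group cost summary (one row of a report table)."""

    group: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    total: float


@dataclass(frozen=True)
class BenchmarkComparison:
    """Signed percent difference of a model value against a reference."""

    label: str
    model_value: float
    reference_value: float
    percent_difference: float


def summarize(
    records: pd.DataFrame, group_key: str, value: str = "total"
) -> pd.DataFrame:
    """Mean/SD/95% CI/total of ``value`` per level of ``group_key``.

    Empty groups are omitted; a single-record group gets SD 0 with a
    logged warning.  The CI is mean +/- 1.96 * SD / sqrt(n).
    """
    rows = []
    for group, sub in records.groupby(group_key, sort=False):
        vals = sub[value].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n < 2:
            logger.warning(
                "group %r has a single record; SD reported as 0", group
            )
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        ci_low, ci_high = normal_ci(mean, sd, n)
        rows.append(
            {
                "group": group,
                "n": n,
                "mean": mean,
                "sd": sd,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "total": mean * n,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty and group_key == "stage":
        order = {s.value: s.order for s in Stage}
        out = out.sort_values("group", key=lambda c: c.map(order)).reset_index(
            drop=True
        )
    return out


def phase_records(records: pd.DataFrame, invasive_only: bool = True) -> pd.DataFrame:
    """Long-format phase-attributed records for phase-level summaries.

    One row per (patient, phase) for the phases the patient actually
    occupies: survivors contribute initial and intermediate rows,
    decedents a terminal row.  Feed the result to :func:`summarize` with
    ``group_key="phase"``.
    """
    df = records
    if invasive_only:
        df = df[df["stage"] != Stage.DCIS.value]
    survivors = df[~df["dies_of_bc"]]
    decedents = df[df["dies_of_bc"]]
    parts = []
    for phase, sub in (
        ("initial", survivors),
        ("intermediate", survivors),
        ("terminal", decedents),
    ):
        if len(sub) == 0:
            logger.warning("phase %r has no records; omitted", phase)
            continue
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": sub["patient_id"].to_numpy(),
                    "stage": sub["stage"].to_numpy(),
                    "phase": phase,
                    "total": sub[phase].to_numpy(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def percent_increase_vs_reference(
    means: Mapping[Stage | str, float], reference: Stage | str = Stage.I
) -> dict[str, float]:
    """Percent increase of each stage mean over the reference stage,
    reported to one decimal."""
    key = reference.value if isinstance(reference, Stage) else str(reference)
    means = {
        (k.value if isinstance(k, Stage) else str(k)): float(v)
        for k, v in means.items()
    }
    ref = means[key]
    if ref == 0:
        raise ValueError("reference mean must be non-zero")
    return {
        k: round((v - ref) / ref * 100.0, 1) for k, v in means.items() if k != key
    }


def national_total(mean: float, n: int) -> float:
    """National cost total: mean per-patient cost times incident cases."""
    if n < 0:
        raise ValueError("case count must be non-negative")
    return mean * n


def component_shares(
    records: pd.DataFrame, chemo_includes_adverse_events: bool = False
) -> pd.Series:
    """Fraction of total realized cost by care component (sums to 1).

    With ``chemo_includes_adverse_events`` the chemotherapy-induced-event
    columns are folded into the chemotherapy share, mirroring how
    cost-driver statements usually bundle them.
    """
    cols = [c.value for c in Component if c.value in records.columns]
    sums = records[cols].sum()
    total = sums.sum()
    if total <= 0:
        raise ValueError("total realized cost is zero; shares undefined")
    shares = sums / total
    if chemo_includes_adverse_events:
        ae_cols = [c.value for c in ADVERSE_EVENT_COMPONENTS]
        shares[Component.CHEMOTHERAPY.value] += shares[ae_cols].sum()
        shares = shares.drop(ae_cols)
    return shares


def compare_to_benchmark(
    model_value: float, reference_value: float, label: str = ""
) -> BenchmarkComparison:
    """Signed percent difference of a model estimate vs a published value."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    pct = (model_value - reference_value) / reference_value * 100.0
    return BenchmarkComparison(
        label=label,
        model_value=model_value,
        reference_value=reference_value,
        percent_difference=pct,
    )


def load_benchmarks() -> pd.DataFrame:
    """Published German phase-of-care benchmarks shipped with the package."""
    ref = resources.files("bccost.data").joinpath("benchmarks.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")
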