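"""Incremental cost-effectiveness analysis between the two arms.

The outcome measure is hip fractures avoided (optionally hip + vertebral
when the vertebral-fracture variant is active); the ICER is expressed in €
per avoided fracture and always computed on unrounded totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .markov import CohortTrace, run_cohort
from .parameters import ParameterSet

__all__ = ["ArmSummary", "CEAResult", "compare", "run_cea", "table_report"]


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm expected totals per person over the model horizon."""

    arm: str
    total_cost: float
    cost_intervention: float
    cost_treatment: float
    cost_ltc: float
    cost_vertebral: float
    hip_fractures: float
    refractures: float
    vert_fractures: float
    nh_admissions: float

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "ArmSummary":
        return cls(
            arm=trace.arm,
            total_cost=trace.cum_cost,
            cost_intervention=trace.cost_intervention,
            cost_treatment=trace.cost_treatment,
            cost_ltc=trace.cost_ltc,
            cost_vertebral=trace.cost_vertebral,
            hip_fractures=trace.cum_hip_fractures,
            refractures=trace.cum_refractures,
            vert_fractures=trace.cum_vert_fractures,
            nh_admissions=trace.cum_nh_admissions,
        )


@dataclass(frozen=True)
class CEAResult:
    """Increments and ICER of the intervention versus no intervention.

    ``status`` is one of ``"icer"`` (positive cost, fractures averted),
    ``"dominant"`` (cost-saving and fracture-averting), ``"dominated"``
    (more costly, more fractures), ``"undefined"`` (extra cost, nothing
    averted) or ``"cost_saving_tradeoff"`` (cheaper but more fractures —
    the south-west quadrant).  ``icer`` is ``None`` unless status is
    ``"icer"``; ``icer_value`` always carries the signed ratio for ranking
    purposes (NaN when no fractures are averted or added).
    """

    fpe: ArmSummary
    reference: ArmSummary
    effect_measure: str = "hip"

    @property
    def d_cost(self) -> float:
        return self.fpe.total_cost - self.reference.total_cost

    def _effect(self, arm: ArmSummary) -> float:
        if self.effect_measure == "hip+vert":
            return arm.hip_fractures + arm.vert_fractures
        return arm.hip_fractures

    @property
    def d_fractures(self) -> float:
        return self._effect(self.fpe) - self._effect(self.reference)

    @property
    def fractures_averted(self) -> float:
        return -self.d_fractures

    @property
    def d_nh_admissions(self) -> float:
        return self.fpe.nh_admissions - self.reference.nh_admissions

    @property
    def status(self) -> str:
        averted = self.fractures_averted
        if averted > 0:
            return "icer" if self.d_cost > 0 else "dominant"
        if self.d_cost > 0:
            return "dominated" if averted < 0 else "undefined"
        return "cost_saving_tradeoff" if averted < 0 else "undefined"

    @property
    def icer(self) -> float | None:
        if self.status != "icer":
            return None
        return self.d_cost / self.fractures_averted

    @property
    def icer_value(self) -> float:
        """Signed Δcost / averted ratio (NaN when the denominator is 0)."""
        if self.fractures_averted == 0:
            return float("nan")
        return self.d_cost / self.fractures_averted


def compare(trace_fpe: CohortTrace, trace_ref: CohortTrace,
            effect_measure: str = "hip") -> CEAResult:
    """Incremental analysis of two cohort traces from the same inputs."""
    if trace_fpe.sex != trace_ref.sex:
        raise ValueError("traces compare different sexes")
    if len(trace_fpe.ages) != len(trace_ref.ages):
        raise ValueError("traces have different horizons")
    return CEAResult(
        fpe=ArmSummary.from_trace(trace_fpe),
        reference=ArmSummary.from_trace(trace_ref),
        effect_measure=effect_measure,
    )


def run_cea(params: ParameterSet, sex: str | None = None,
            effect_measure: str | None = None) -> CEAResult:
    """Run both arms of the model and compare them."""
    if effect_measure is None:
        effect_measure = (
            "hip+vert" if (params.variant or {}).get("id") == "II" else "hip"
        )
    fpe = run_cohort(params, "fpe", sex=sex)
    ref = run_cohort(params, "no-fpe", sex=sex)
    return compare(fpe, ref, effect_measure=effect_measure)


def table_report(result: CEAResult) -> pd.DataFrame:
    """Base-case results in the conventional row layout.

    One row per arm plus the increment row; costs rounded to whole euros,
    outcome proportions to 4 decimals, the ICER computed from the unrounded
    increments.
    """
    rows = []
    for arm in (result.fpe, result.reference):
        rows.append({
            "row": arm.arm,
            "total_cost": round(arm.total_cost),
            "cost_intervention": round(arm.cost_intervention),
            "cost_treatment": round(arm.cost_treatment),
            "cost_ltc": round(arm.cost_ltc),
            "hip_fractures": round(arm.hip_fractures, 4),
            "refractures": round(arm.refractures, 4),
            "nh_admissions": round(arm.nh_admissions, 4),
            "icer": "",
        })
    rows.append({
        "row": "difference",
        "total_cost": round(result.d_cost),
        "cost_intervention": round(result.fpe.cost_intervention
                                   - result.reference.cost_intervention),
        "cost_treatment": round(result.fpe.cost_treatment
                                - result.reference.cost_treatment),
        "cost_ltc": round(result.fpe.cost_ltc - result.reference.cost_ltc),
        "hip_fractures": round(result.d_fractures, 4),
        "refractures": round(result.fpe.refractures - result.reference.refractures, 4),
        "nh_admissions": round(result.d_nh_admissions, 4),
        "icer": round(result.icer) if result.icer is not None else result.status,
    })
    return pd.DataFrame(rows)
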