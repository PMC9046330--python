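"""Cost-utility aggregation: totals, increments, NMB/iNMB and dominance.

Net monetary benefit converts QALYs to dollars at the willingness-to-pay
threshold: NMB = WTP * QALYs - cost.  The incremental NMB between arms
is the decision statistic; the ICER (delta cost / delta QALYs) is only
reported as a number in the trade-off quadrants — when one arm is both
cheaper and more effective it is flagged as dominant instead, since a
negative ratio has no interpretation.

All internal comparisons use full precision; rounding to whole dollars
and two-decimal QALYs happens only in the reporting layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .engine import CohortTrace, run_cohort
from .errors import IncompatibleTraceError
from .parameters import ModelParameters
from .states import Arm

__all__ = ["nmb", "compare_arms", "run_base_case", "ArmResult", "CUAResult", "Dominance", "results_frame"]


class Dominance(str, enum.Enum):
    INTERVENTION_DOMINANT = "intervention_dominant"
    CONTROL_DOMINANT = "control_dominant"
    TRADE_OFF = "trade_off"


def nmb(total_cost, total_qalys, wtp) -> float:
    """Net monetary benefit: wtp * total_qalys - total_cost."""
    if np.any(np.asarray(wtp) < 0):
        raise ValueError("wtp must be non-negative")
    return wtp * total_qalys - total_cost


@dataclass(frozen=True)
class ArmResult:
    arm: Arm
    total_cost: float
    total_qalys: float
    nmb: float


@dataclass(frozen=True)
class CUAResult:
    control: ArmResult
    intervention: ArmResult
    delta_cost: float
    delta_qalys: float
    inmb: float
    icer: Union[float, str]
    dominance: Dominance
    wtp: float


def _arm_result(trace: CohortTrace, wtp: float) -> ArmResult:
    cost = float(trace.total_cost)
    qalys = float(trace.total_qalys)
    return ArmResult(arm=trace.arm, total_cost=cost, total_qalys=qalys, nmb=float(nmb(cost, qalys, wtp)))


def compare_arms(
    trace_control: CohortTrace, trace_intervention: CohortTrace, wtp: float
) -> CUAResult:
    """Base-case comparison of two single-run traces at a WTP threshold."""
    if (
        trace_control.horizon_years != trace_intervention.horizon_years
        or trace_control.cycle_months != trace_intervention.cycle_months
    ):
        raise IncompatibleTraceError("traces were run over different horizons")
    if trace_control.arm is not Arm.CONTROL or trace_intervention.arm is not Arm.INTERVENTION:
        raise IncompatibleTraceError("traces passed in the wrong arm order")

    ctl = _arm_result(trace_control, wtp)
    ivn = _arm_result(trace_intervention, wtp)
    delta_cost = ivn.total_cost - ctl.total_cost
    delta_qalys = ivn.total_qalys - ctl.total_qalys
    inmb = ivn.nmb - ctl.nmb

    if delta_cost < 0 and delta_qalys > 0:
        dominance = Dominance.INTERVENTION_DOMINANT
        icer: Union[float, str] = "intervention_dominant"
    elif delta_cost > 0 and delta_qalys < 0:
        dominance = Dominance.CONTROL_DOMINANT
        icer = "control_dominant"
    else:
        dominance = Dominance.TRADE_OFF
        icer = float("nan") if delta_qalys == 0 else delta_cost / delta_qalys

    return CUAResult(
        control=ctl,
        intervention=ivn,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        inmb=inmb,
        icer=icer,
        dominance=dominance,
        wtp=float(wtp),
    )


def run_base_case(params: ModelParameters, wtp: float = None) -> CUAResult:
    """Run both arms through the cohort engine and compare them."""
    params.validate()
    wtp = params.wtp if wtp is None else wtp
    return compare_arms(
        run_cohort(params, Arm.CONTROL), run_cohort(params, Arm.INTERVENTION), wtp
    )


def results_frame(result: CUAResult) -> pd.DataFrame:
    """Reporting table (whole dollars, two-decimal QALYs)."""
    rows = []
    for arm_res in (result.control, result.intervention):
        rows.append(
            {
                "arm": arm_res.arm.value,
                "mean_cost_aud": round(arm_res.total_cost),
                "mean_qalys": round(arm_res.total_qalys, 2),
                "nmb_aud": round(arm_res.nmb),
            }
        )
    rows.append(
        {
            "arm": "difference",
            "mean_cost_aud": round(result.delta_cost),
            "mean_qalys": round(result.delta_qalys, 2),
            "nmb_aud": round(result.inmb),
        }
    )
    frame = pd.DataFrame(rows)
    frame["dominance"] = result.dominance.value
    frame["icer"] = (
        result.icer if isinstance(result.icer, str) else round(float(result.icer))
    )
    return frame
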