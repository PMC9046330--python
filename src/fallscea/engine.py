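"""Cohort state-transition engine.

Builds per-cycle, per-arm transition matrices over the seven operational
states and propagates a cohort through them, accumulating discounted,
half-cycle-corrected cost and QALY rewards.

Structural assumptions (see docs/methods.md for the full rationale):

* Annual probabilities convert to per-cycle ones with the constant-rate
  transform ``1 - (1 - p)**f``.
* The exercise relative risk for falls applies to the probability of a
  first fall in a year; the recurrent-fall probability is arm-independent.
* Conditional on a fall: a fracture occurs with the annual fracture
  probability (its exercise RR is a marginal-risk ratio, so the
  conditional reduction is ``rr_fracture / rr_fall``); non-fracture
  fallers sustain an injury with ``p_nonfx_injury`` (times the injury RR
  in the exercise arm); major/minor splits apply within each branch.
* Only major events can be fatal: entrants to a major fracture or major
  injury die at event time with the age-band case fatality, in which
  case no tunnel cost or utility accrues.
* Non-fallers and tunnel occupants face per-cycle background mortality.
* Tunnel states last one cycle and exit to the recurrent-risk state.
* One-off treatment costs are charged on tunnel entry, discounted at the
  entry row; the intervention cost is charged upfront, undiscounted.

All operations broadcast: parameter fields may be scalars or arrays of
per-draw values, in which case every returned quantity gains the same
leading batch dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import InfeasibleDecompositionError
from .parameters import ModelParameters
from .states import Arm, HealthState, N_STATES, STATE_LABELS, TUNNEL_STATES

__all__ = [
    "annual_to_cycle_prob",
    "fall_outcome_distribution",
    "build_transition_matrix",
    "run_cohort",
    "TransitionMatrix",
    "CohortTrace",
    "trace_frame",
]

_S = HealthState


def annual_to_cycle_prob(p_annual, cycle_fraction: float):
    """Convert an annual probability to a shorter-cycle one.

    Uses the constant-rate assumption ``1 - (1 - p)**f``; monotone
    increasing in both arguments and exact at the endpoints 0 and 1.
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p_annual must lie in [0, 1]")
    if not 0.0 < cycle_fraction <= 1.0:
        raise ValueError("cycle_fraction must lie in (0, 1]")
    out = 1.0 - (1.0 - p) ** cycle_fraction
    return out if out.ndim else float(out)


def _is_exercise(arm: Union[Arm, str]) -> bool:
    return Arm(arm) is Arm.INTERVENTION


def _conditional_event_probs(params: ModelParameters, arm):
    """(P(fracture | fall), P(injury | non-fracture fall)) for an arm."""
    if _is_exercise(arm):
        q_fx = np.asarray(
            params.p_fracture_annual
            * params.rr_fracture_exercise
            / params.rr_fall_exercise,
            dtype=float,
        )
        p_inj = np.asarray(params.p_nonfx_injury * params.rr_injury_exercise, dtype=float)
    else:
        q_fx = np.asarray(params.p_fracture_annual, dtype=float)
        p_inj = np.asarray(params.p_nonfx_injury, dtype=float)
    if np.any(q_fx > 1.0):
        raise InfeasibleDecompositionError(
            "conditional fracture probability p_fracture_annual * "
            "rr_fracture_exercise / rr_fall_exercise exceeds 1"
        )
    if np.any(p_inj > 1.0):
        raise InfeasibleDecompositionError(
            "conditional injury probability p_nonfx_injury * rr_injury_exercise exceeds 1"
        )
    return q_fx, p_inj


def fall_outcome_distribution(params: ModelParameters, arm, age: float) -> np.ndarray:
    """Distribution over destination states conditional on a fall.

    Returns an array whose last axis indexes :class:`HealthState`; the
    two at-risk components are 0 except for the uninjured remainder,
    which moves to the recurrent-risk state.  Rows sum to 1.
    """
    q_fx, p_inj = _conditional_event_probs(params, arm)
    p_death = np.asarray(params.fall_death_at(age), dtype=float)

    fx_major = q_fx * params.p_fx_major
    fx_minor = q_fx * params.p_fx_minor
    non_fx = 1.0 - q_fx
    inj_major = non_fx * p_inj * params.p_inj_major
    inj_minor = non_fx * p_inj * params.p_inj_minor

    shape = np.broadcast_shapes(
        np.shape(fx_major),
        np.shape(fx_minor),
        np.shape(inj_major),
        np.shape(inj_minor),
        np.shape(p_death),
    )
    dist = np.zeros(shape + (N_STATES,))
    dist[..., _S.FRACTURE_MAJOR] = fx_major * (1.0 - p_death)
    dist[..., _S.FRACTURE_MINOR] = fx_minor
    dist[..., _S.INJURY_MAJOR] = inj_major * (1.0 - p_death)
    dist[..., _S.INJURY_MINOR] = inj_minor
    dist[..., _S.AT_RISK_RECURRENT] = non_fx * (1.0 - p_inj)
    dist[..., _S.DEAD] = (fx_major + inj_major) * p_death
    return dist


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-cycle transition matrix for one arm and cycle."""

    cycle_index: int
    arm: Arm
    probs: np.ndarray  # (..., 7, 7)


def build_transition_matrix(
    params: ModelParameters, arm, cycle_index: int
) -> TransitionMatrix:
    """Transition matrix for the given cycle, with age-updated mortality."""
    if not 0 <= cycle_index < params.n_cycles:
        raise ValueError(f"cycle_index {cycle_index} outside [0, {params.n_cycles})")
    arm = Arm(arm)
    f = params.cycle_fraction
    age = params.start_age + cycle_index * f
    q_bg = annual_to_cycle_prob(params.background_mortality_at(age), f)

    dist = fall_outcome_distribution(params, arm, age)
    rr_fall = params.rr_fall_exercise if _is_exercise(arm) else 1.0
    p_fall_first = annual_to_cycle_prob(params.p_fall_year1 * rr_fall, f)
    p_fall_rec = annual_to_cycle_prob(params.p_fall_recurrent, f)

    shape = np.broadcast_shapes(
        dist.shape[:-1], np.shape(p_fall_first), np.shape(p_fall_rec), np.shape(q_bg)
    )
    M = np.zeros(shape + (N_STATES, N_STATES))
    for row, p_fall in (
        (_S.AT_RISK_FIRST, p_fall_first),
        (_S.AT_RISK_RECURRENT, p_fall_rec),
    ):
        p_fall = np.asarray(p_fall)
        M[..., row, :] = p_fall[..., None] * dist
        M[..., row, _S.DEAD] += (1.0 - p_fall) * q_bg
        M[..., row, row] += (1.0 - p_fall) * (1.0 - q_bg)
    for s in TUNNEL_STATES:
        M[..., s, _S.AT_RISK_RECURRENT] = 1.0 - q_bg
        M[..., s, _S.DEAD] = q_bg
    M[..., _S.DEAD, _S.DEAD] = 1.0
    return TransitionMatrix(cycle_index=cycle_index, arm=arm, probs=M)


# ----- reward machinery shared with the microsimulation -----


def discount_factors(params: ModelParameters, n_rows: int) -> np.ndarray:
    """Per-row discount factors (1 + r)^(-t * cycle_fraction)."""
    t = np.arange(n_rows)
    return (1.0 + params.discount_annual) ** (-t * params.cycle_fraction)


def halfcycle_weights(n_rows: int) -> np.ndarray:
    """Life-table half-cycle correction: half weight on the end rows."""
    w = np.ones(n_rows)
    w[0] = w[-1] = 0.5
    return w


def utility_vector(params: ModelParameters, arm) -> np.ndarray:
    """Per-state utilities (last axis indexes states); DEAD has 0."""
    u_rec = (
        params.u_recurrent_exercise if _is_exercise(arm) else params.u_recurrent_control
    )
    parts = np.broadcast_arrays(
        np.asarray(params.u_baseline, dtype=float),
        np.asarray(u_rec, dtype=float),
        np.asarray(params.u_fx_major, dtype=float),
        np.asarray(params.u_fx_minor, dtype=float),
        np.asarray(params.u_inj_major, dtype=float),
        np.asarray(params.u_inj_minor, dtype=float),
        np.asarray(0.0),
    )
    return np.stack(parts, axis=-1)


def event_cost_vector(params: ModelParameters) -> np.ndarray:
    """One-off treatment cost charged on entry into each state (0 elsewhere)."""
    zero = np.asarray(0.0)
    parts = np.broadcast_arrays(
        zero,
        zero,
        np.asarray(params.c_fx_major, dtype=float),
        np.asarray(params.c_fx_minor, dtype=float),
        np.asarray(params.c_inj_major, dtype=float),
        np.asarray(params.c_inj_minor, dtype=float),
        zero,
    )
    return np.stack(parts, axis=-1)


@dataclass
class CohortTrace:
    """State occupancy and discounted per-cycle rewards for one arm."""

    arm: Arm
    occupancy: np.ndarray  # (..., n_cycles + 1, 7); row 0 all in AT_RISK_FIRST
    cycle_qalys: np.ndarray  # (..., n_cycles + 1) discounted, half-cycle weighted
    one_off_costs: np.ndarray  # (..., n_cycles + 1) discounted event costs
    cycle_costs: np.ndarray  # one_off_costs plus the upfront intervention cost
    horizon_years: int
    cycle_months: int
    wtp: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[-2] - 1

    @property
    def total_cost(self):
        return self.cycle_costs.sum(axis=-1)

    @property
    def total_qalys(self):
        return self.cycle_qalys.sum(axis=-1)

    @property
    def life_years_undiscounted(self):
        alive = 1.0 - self.occupancy[..., HealthState.DEAD]
        w = halfcycle_weights(self.occupancy.shape[-2])
        return (alive * w).sum(axis=-1) * self.cycle_months / 12.0


def run_cohort(params: ModelParameters, arm) -> CohortTrace:
    """Propagate the cohort over the full horizon and accumulate rewards."""
    arm = Arm(arm)
    n = params.n_cycles
    f = params.cycle_fraction
    d = discount_factors(params, n + 1)
    w = halfcycle_weights(n + 1)
    u = utility_vector(params, arm)
    c = event_cost_vector(params)

    # probe one matrix to learn the batch shape
    M0 = build_transition_matrix(params, arm, 0).probs
    batch = M0.shape[:-2]
    occ = np.zeros(batch + (n + 1, N_STATES))
    occ[..., 0, HealthState.AT_RISK_FIRST] = 1.0
    for t in range(n):
        M = M0 if t == 0 else build_transition_matrix(params, arm, t).probs
        occ[..., t + 1, :] = np.einsum("...i,...ij->...j", occ[..., t, :], M)

    membership_u = (occ * u[..., None, :]).sum(axis=-1)  # (..., n+1)
    cycle_qalys = membership_u * f * w * d

    one_off = (occ * c[..., None, :]).sum(axis=-1) * d
    one_off[..., 0] = 0.0  # row 0 has no event entrants
    cycle_costs = one_off.copy()
    if _is_exercise(arm):
        cycle_costs[..., 0] = cycle_costs[..., 0] + params.c_intervention

    return CohortTrace(
        arm=arm,
        occupancy=occ,
        cycle_qalys=cycle_qalys,
        one_off_costs=one_off,
        cycle_costs=cycle_costs,
        horizon_years=params.horizon_years,
        cycle_months=params.cycle_months,
        wtp=float(params.wtp),
    )


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Per-cycle trace as a tidy table (scalar parameter sets only)."""
    if trace.occupancy.ndim != 2:
        raise ValueError("trace_frame requires a scalar (non-batched) trace")
    n_rows = trace.occupancy.shape[0]
    data = {"cycle": np.arange(n_rows), "arm": trace.arm.value}
    for state in HealthState:
        data[STATE_LABELS[state]] = trace.occupancy[:, state]
    data["discounted_cost"] = trace.cycle_costs
    data["discounted_qalys"] = trace.cycle_qalys
    data["cumulative_cost"] = np.cumsum(trace.cycle_costs)
    data["cumulative_qalys"] = np.cumsum(trace.cycle_qalys)
    return pd.DataFrame(data)
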