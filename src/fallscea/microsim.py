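"""Individual-level Monte Carlo twin of the cohort engine.

Simulates single patients through the identical stochastic process the
cohort model integrates analytically: per-cycle fall events, conditional
fracture/injury/death outcomes, state utilities with half-cycle
weighting, one-off event costs and discounting.  By the law of large
numbers its mean cost and QALYs converge to the cohort totals at the
1/sqrt(n) rate, which makes it the package's strongest correctness check
— any disagreement beyond Monte Carlo error isolates a bug on one side.

Two sampling modes are provided:

* ``"matrix"`` (default) draws each person's next state from the very
  transition-matrix rows the cohort engine multiplies, so discrepancies
  isolate reward-accumulation bugs rather than probability construction;
* ``"event"`` re-derives every branch probability independently (fall,
  fracture, severity, death, injury) for an end-to-end cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .engine import (
    annual_to_cycle_prob,
    build_transition_matrix,
    discount_factors,
    event_cost_vector,
    halfcycle_weights,
    run_cohort,
    utility_vector,
)
from .parameters import ModelParameters
from .states import Arm, HealthState, STATE_LABELS, TUNNEL_STATES

__all__ = ["simulate_individuals", "compare_to_cohort", "MicrosimResult", "trajectories_frame"]

_S = HealthState
_TUNNEL_IDX = np.array([int(s) for s in TUNNEL_STATES])


@dataclass
class MicrosimResult:
    arm: Arm
    costs: np.ndarray  # realized discounted cost per person
    qalys: np.ndarray  # realized discounted QALYs per person
    trajectories: np.ndarray  # (n, n_cycles + 1) state indices

    @property
    def n(self) -> int:
        return len(self.costs)

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def se_cost(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(self.n))

    @property
    def mean_qalys(self) -> float:
        return float(self.qalys.mean())

    @property
    def se_qalys(self) -> float:
        return float(self.qalys.std(ddof=1) / np.sqrt(self.n))


def _per_person(value, n: int) -> np.ndarray:
    """Broadcast a scalar or per-person parameter field to shape (n,)."""
    arr = np.asarray(value, dtype=float)
    return np.broadcast_to(arr, (n,))


def _draw_next_matrix(rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample destination states from per-person probability rows."""
    cum = np.cumsum(rows, axis=-1)
    nxt = (u[:, None] > cum).sum(axis=-1)
    return np.minimum(nxt, len(HealthState) - 1)


def simulate_individuals(
    params: ModelParameters, arm, n: int, seed: int, mode: str = "matrix"
) -> MicrosimResult:
    """Simulate ``n`` independent patients through one arm.

    Parameter fields may be per-person arrays of length ``n`` (used by
    the probabilistic sensitivity analysis in individual mode).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("matrix", "event"):
        raise ValueError(f"unknown mode {mode!r}")
    arm = Arm(arm)
    ex = arm is Arm.INTERVENTION
    rng = np.random.default_rng(seed)

    nc = params.n_cycles
    f = params.cycle_fraction
    d = discount_factors(params, nc + 1)
    w = halfcycle_weights(nc + 1)
    u_states = utility_vector(params, arm)  # (7,) or (n, 7)
    c_states = event_cost_vector(params)
    if u_states.ndim == 1:
        u_states = np.broadcast_to(u_states, (n, len(HealthState)))
    if c_states.ndim == 1:
        c_states = np.broadcast_to(c_states, (n, len(HealthState)))
    persons = np.arange(n)

    state = np.full(n, int(_S.AT_RISK_FIRST), dtype=np.int8)
    traj = np.zeros((n, nc + 1), dtype=np.int8)
    costs = np.zeros(n)
    qalys = np.zeros(n)

    for t in range(nc + 1):
        traj[:, t] = state
        qalys += w[t] * d[t] * f * u_states[persons, state]
        if t > 0:
            in_tunnel = np.isin(state, _TUNNEL_IDX)
            costs[in_tunnel] += d[t] * c_states[persons[in_tunnel], state[in_tunnel]]
        if t == nc:
            break
        if mode == "matrix":
            state = _step_matrix(params, arm, t, state, rng, n)
        else:
            state = _step_event(params, ex, t, state, rng, n)

    if ex:
        costs = costs + _per_person(params.c_intervention, n)
    return MicrosimResult(arm=arm, costs=costs, qalys=qalys, trajectories=traj)


def _step_matrix(params, arm, t, state, rng, n):
    probs = build_transition_matrix(params, arm, t).probs
    if probs.ndim == 2:
        rows = probs[state]
    else:
        rows = probs[np.arange(n), state]
    return _draw_next_matrix(rows, rng.random(n)).astype(np.int8)


def _step_event(params, ex, t, state, rng, n):
    """Hierarchical branch draws; probabilities re-derived from scratch."""
    f = params.cycle_fraction
    age = params.start_age + t * f
    q_bg = _per_person(annual_to_cycle_prob(params.background_mortality_at(age), f), n)
    p_death = _per_person(params.fall_death_at(age), n)
    rr_fall = params.rr_fall_exercise if ex else 1.0
    p_fall_first = _per_person(
        1.0 - (1.0 - np.asarray(params.p_fall_year1, dtype=float) * rr_fall) ** f, n
    )
    p_fall_rec = _per_person(
        1.0 - (1.0 - np.asarray(params.p_fall_recurrent, dtype=float)) ** f, n
    )
    if ex:
        q_fx = _per_person(
            np.asarray(params.p_fracture_annual, dtype=float)
            * params.rr_fracture_exercise
            / params.rr_fall_exercise,
            n,
        )
        p_inj = _per_person(
            np.asarray(params.p_nonfx_injury, dtype=float) * params.rr_injury_exercise, n
        )
    else:
        q_fx = _per_person(params.p_fracture_annual, n)
        p_inj = _per_person(params.p_nonfx_injury, n)
    p_fx_major = _per_person(params.p_fx_major, n)
    p_inj_major = _per_person(params.p_inj_major, n)

    new = state.copy()
    at_risk = (state == _S.AT_RISK_FIRST) | (state == _S.AT_RISK_RECURRENT)
    p_fall = np.where(state == _S.AT_RISK_FIRST, p_fall_first, p_fall_rec)
    fell = at_risk & (rng.random(n) < p_fall)

    # non-fallers: background mortality, else remain in place
    bg_die = rng.random(n) < q_bg
    stay = at_risk & ~fell
    new[stay & bg_die] = _S.DEAD

    # fallers: fracture branch, then injury branch, then uninjured
    fractured = fell & (rng.random(n) < q_fx)
    major_fx = rng.random(n) < p_fx_major
    new[fractured & ~major_fx] = _S.FRACTURE_MINOR
    fatal = rng.random(n) < p_death
    new[fractured & major_fx & ~fatal] = _S.FRACTURE_MAJOR
    new[fractured & major_fx & fatal] = _S.DEAD

    not_fx = fell & ~fractured
    injured = not_fx & (rng.random(n) < p_inj)
    major_inj = rng.random(n) < p_inj_major
    new[injured & ~major_inj] = _S.INJURY_MINOR
    new[injured & major_inj & ~fatal] = _S.INJURY_MAJOR
    new[injured & major_inj & fatal] = _S.DEAD
    new[not_fx & ~injured] = _S.AT_RISK_RECURRENT

    # tunnel occupants exit to recurrent risk unless background death
    in_tunnel = np.isin(state, _TUNNEL_IDX)
    new[in_tunnel & ~bg_die] = _S.AT_RISK_RECURRENT
    new[in_tunnel & bg_die] = _S.DEAD
    return new


@dataclass
class CohortAgreementReport:
    """Per-arm z-scores of microsim means against cohort-engine totals."""

    n: int
    z_scores: Dict[str, float]  # e.g. {"control_cost": ..., "intervention_qalys": ...}

    @property
    def max_abs_z(self) -> float:
        return max(abs(z) for z in self.z_scores.values())

    def passed(self, threshold: float = 3.0) -> bool:
        return self.max_abs_z < threshold


def compare_to_cohort(
    params: ModelParameters, n: int, seed: int, mode: str = "matrix"
) -> CohortAgreementReport:
    """Check microsim means against the cohort engine, both arms."""
    z: Dict[str, float] = {}
    seeds = np.random.SeedSequence(seed).generate_state(2)
    for arm, arm_seed in zip((Arm.CONTROL, Arm.INTERVENTION), seeds):
        trace = run_cohort(params, arm)
        sim = simulate_individuals(params, arm, n, int(arm_seed), mode=mode)
        z[f"{arm.value}_cost"] = (sim.mean_cost - float(trace.total_cost)) / sim.se_cost
        z[f"{arm.value}_qalys"] = (sim.mean_qalys - float(trace.total_qalys)) / sim.se_qalys
    return CohortAgreementReport(n=n, z_scores=z)


def trajectories_frame(result: MicrosimResult) -> pd.DataFrame:
    """Long-format (person, cycle, state) table for debugging."""
    n, n_rows = result.trajectories.shape
    return pd.DataFrame(
        {
            "person": np.repeat(np.arange(n), n_rows),
            "cycle": np.tile(np.arange(n_rows), n),
            "state": [
                STATE_LABELS[HealthState(s)] for s in result.trajectories.ravel()
            ],
        }
    )
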