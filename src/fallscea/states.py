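"""Health states of the falls/fracture Markov model.

The model tracks a cohort of men starting androgen deprivation therapy
through seven operational states.  ``FRACTURE_*`` and ``INJURY_*`` are
single-cycle (tunnel) states: a person occupies them for exactly one
3-month cycle — the typical recovery period — and then returns to the
recurrent-risk state or dies.  ``DEAD`` is absorbing.
"""

from __future__ import annotations

import enum


class Arm(str, enum.Enum):
    """Comparator arms of the evaluation."""

    CONTROL = "control"
    INTERVENTION = "intervention"


class HealthState(enum.IntEnum):
    AT_RISK_FIRST = 0
    AT_RISK_RECURRENT = 1
    FRACTURE_MAJOR = 2
    FRACTURE_MINOR = 3
    INJURY_MAJOR = 4
    INJURY_MINOR = 5
    DEAD = 6


N_STATES = len(HealthState)

#: tunnel states: occupied for exactly one cycle, with a one-off treatment cost
TUNNEL_STATES = (
    HealthState.FRACTURE_MAJOR,
    HealthState.FRACTURE_MINOR,
    HealthState.INJURY_MAJOR,
    HealthState.INJURY_MINOR,
)

STATE_LABELS = {
    HealthState.AT_RISK_FIRST: "at_risk_first_fall",
    HealthState.AT_RISK_RECURRENT: "at_risk_recurrent_fall",
    HealthState.FRACTURE_MAJOR: "fracture_major",
    HealthState.FRACTURE_MINOR: "fracture_minor",
    HealthState.INJURY_MAJOR: "injury_major",
    HealthState.INJURY_MINOR: "injury_minor",
    HealthState.DEAD: "dead",
}
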