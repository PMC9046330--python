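"""Deterministic sensitivity analysis: one-way (tornado) and scenarios.

One-way analysis re-runs the full base case twice per parameter, pinned
to the lower and upper bound of its published 95% CI with everything
else at its mean; the spread |iNMB(high) - iNMB(low)| ranks parameters
for a tornado diagram.  The major/minor event splits are varied through
their "major" share with the complement adjusted, preserving the
sum-to-one constraint, so the minor shares are not separate entries.

Scenario analysis applies named parameter overrides (for example the
costed alternative intervention deliveries) and re-runs the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import pandas as pd

from .cua import CUAResult, run_base_case
from .errors import MissingRangeError
from .parameters import FALL_DEATH_BANDS, ModelParameters, ScenarioOverride

__all__ = [
    "TornadoEntry",
    "univariate_sa",
    "run_scenario",
    "tornado_frame",
    "COST_SCENARIOS",
    "default_sa_parameters",
]

#: alternative intervention-delivery costings (2019 AUD per participant):
#: groups of six with out-of-pocket travel/gym costs (SA2a); group exercise
#: delivered under the chronic-disease MBS item (SA4); SA4 plus the same
#: out-of-pocket costs (SA4a).
COST_SCENARIOS = {
    "SA2a": ScenarioOverride("SA2a", {"c_intervention": 2338}),
    "SA4": ScenarioOverride("SA4", {"c_intervention": 2154}),
    "SA4a": ScenarioOverride("SA4a", {"c_intervention": 3304}),
}

# complement pairs: varying the major share moves the minor share with it
_COMPLEMENTS = {"p_fx_major": "p_fx_minor", "p_inj_major": "p_inj_minor"}
_DERIVED = set(_COMPLEMENTS.values())


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


def default_sa_parameters(params: ModelParameters) -> List[str]:
    """All registry parameters with CI bounds, minus derived complements."""
    return [name for name in params.estimates if name not in _DERIVED]


def _pin(params: ModelParameters, name: str, value: float) -> ModelParameters:
    overrides = {name: value}
    partner = _COMPLEMENTS.get(name)
    if partner is not None:
        overrides[partner] = 1.0 - value
    return params.replace(**overrides)


def univariate_sa(
    params: ModelParameters, parameter_list: Optional[Iterable[str]] = None
) -> List[TornadoEntry]:
    """One-way sensitivity of the iNMB; sorted by spread, descending.

    Ties in spread break alphabetically so the ordering is invariant to
    the order of ``parameter_list``.
    """
    params.validate()
    names = list(parameter_list) if parameter_list is not None else default_sa_parameters(params)
    entries = []
    for name in names:
        est = params.estimates.get(name)
        if est is None:
            raise MissingRangeError(f"parameter {name!r} has no CI bounds")
        low = run_base_case(_pin(params, name, est.ci_low)).inmb
        high = run_base_case(_pin(params, name, est.ci_high)).inmb
        entries.append(
            TornadoEntry(
                parameter=name,
                low_value=est.ci_low,
                high_value=est.ci_high,
                inmb_at_low=low,
                inmb_at_high=high,
            )
        )
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def run_scenario(params: ModelParameters, scenario: ScenarioOverride) -> CUAResult:
    """Full base-case pipeline on an overridden parameter set."""
    return run_base_case(scenario.apply(params))


def tornado_frame(entries: List[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "inmb_at_low": [e.inmb_at_low for e in entries],
            "inmb_at_high": [e.inmb_at_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )
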