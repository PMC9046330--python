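"""Model inputs: the parameter registry, validation and config I/O.

Every quantity the model uses is housed here: annual transition
probabilities, exercise relative risks, per-event treatment costs,
health-state utilities, the fall-death case-fatality probabilities by
age band, background mortality, and the run settings (start age,
horizon, cycle length, discount rate, willingness-to-pay).

Uncertain parameters carry a :class:`ParameterEstimate` — mean, 95% CI
and distribution family — from which the PSA samples.  The packaged
default configuration reproduces the published input tables; any value
can be overridden from a YAML/JSON-style mapping or file.
"""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import yaml

from .distributions import FittedDistribution, fit_distribution
from .errors import ConfigError, ValidationError

__all__ = [
    "ParameterEstimate",
    "ModelParameters",
    "ScenarioOverride",
    "load_parameters",
    "dump_parameters",
    "intervention_cost_total",
    "FALL_DEATH_BANDS",
]

_FAMILIES = {"beta", "gamma", "lognormal", "fixed"}

#: age bands (inclusive) for the fall-death case-fatality probabilities
FALL_DEATH_BANDS = ("60_64", "65_69", "70_74")


@dataclass(frozen=True)
class ParameterEstimate:
    """A published point estimate with its 95% CI and PSA distribution family."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    family: str
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValidationError(
                f"{self.name}: mean {self.mean} outside CI ({self.ci_low}, {self.ci_high})"
            )
        if self.family == "beta" and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise ValidationError(f"{self.name}: beta support requires CI within [0, 1]")
        if self.family == "gamma" and self.ci_low < 0.0:
            raise ValidationError(f"{self.name}: gamma support requires ci_low >= 0")
        if self.family == "lognormal" and self.ci_low <= 0.0:
            raise ValidationError(f"{self.name}: lognormal requires ci_low > 0")

    def fit(self) -> FittedDistribution:
        return fit_distribution(self.family, self.mean, self.ci_low, self.ci_high)


# value fields that are annual probabilities / proportions (support [0, 1])
_PROB_FIELDS = (
    "p_fall_year1",
    "p_fall_recurrent",
    "p_fracture_annual",
    "p_fx_major",
    "p_fx_minor",
    "p_nonfx_injury",
    "p_inj_major",
    "p_inj_minor",
)
_RR_FIELDS = ("rr_fall_exercise", "rr_fracture_exercise", "rr_injury_exercise")
_COST_FIELDS = ("c_fx_major", "c_fx_minor", "c_inj_major", "c_inj_minor", "c_intervention")
_UTILITY_FIELDS = (
    "u_baseline",
    "u_fx_major",
    "u_fx_minor",
    "u_inj_major",
    "u_inj_minor",
    "u_recurrent_control",
    "u_recurrent_exercise",
)
VALUE_FIELDS = _PROB_FIELDS + _RR_FIELDS + _COST_FIELDS + _UTILITY_FIELDS
_SETTING_FIELDS = ("start_age", "horizon_years", "cycle_months", "discount_annual", "wtp")


@dataclass
class ModelParameters:
    """The complete, validated input set for one control/intervention pair.

    Value fields may be scalars (base case) or equal-length numpy arrays
    (one entry per PSA draw); the engine broadcasts over them.
    """

    # transition probabilities (12-month) and exercise relative risks
    p_fall_year1: float = 0.36
    p_fall_recurrent: float = 0.65
    rr_fall_exercise: float = 0.76
    p_fracture_annual: float = 0.12
    rr_fracture_exercise: float = 0.44
    p_fx_major: float = 0.62
    p_fx_minor: float = 0.38
    p_nonfx_injury: float = 0.88
    rr_injury_exercise: float = 0.70
    p_inj_major: float = 0.06
    p_inj_minor: float = 0.94
    # probability of death given a major fall event, by age band
    p_death_fall_by_age: Dict[str, float] = field(
        default_factory=lambda: {"60_64": 0.023, "65_69": 0.043, "70_74": 0.065}
    )
    # annual all-cause death probability by completed year of age
    background_mortality: Dict[int, float] = field(default_factory=dict)
    # costs, 2019 AUD
    c_fx_major: float = 20724.0
    c_fx_minor: float = 8797.0
    c_inj_major: float = 10040.0
    c_inj_minor: float = 1115.0
    c_intervention: float = 767.0
    # utilities
    u_baseline: float = 0.79
    u_fx_major: float = 0.475
    u_fx_minor: float = 0.565
    u_inj_major: float = 0.47
    u_inj_minor: float = 0.765
    u_recurrent_control: float = 0.72
    u_recurrent_exercise: float = 0.74
    # run settings
    start_age: float = 68.0
    horizon_years: int = 3
    cycle_months: int = 3
    discount_annual: float = 0.05
    wtp: float = 50000.0
    # provenance registry for uncertain parameters (name -> estimate)
    estimates: Dict[str, ParameterEstimate] = field(default_factory=dict, compare=False)
    intervention_cost_components: Optional[Dict[str, float]] = field(
        default=None, compare=False
    )

    # ----- derived quantities -----

    @property
    def cycle_fraction(self) -> float:
        return self.cycle_months / 12.0

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * 12 / self.cycle_months))

    def fall_death_at(self, age: float):
        """Case fatality of a major fall event at (fractional) age.

        Ages below 65 use the 60-64 band; 65-69 and 70-74 as labelled;
        older ages keep the 70-74 value (the highest tabulated band).
        """
        if age < 65:
            return self.p_death_fall_by_age["60_64"]
        if age < 70:
            return self.p_death_fall_by_age["65_69"]
        return self.p_death_fall_by_age["70_74"]

    def background_mortality_at(self, age: float) -> float:
        """Annual all-cause death probability at completed years of age.

        Ages outside the packaged table are clamped to its first/last row.
        """
        if not self.background_mortality:
            raise ValidationError("background_mortality table is empty")
        year = int(age)
        lo, hi = min(self.background_mortality), max(self.background_mortality)
        return self.background_mortality[min(max(year, lo), hi)]

    # ----- validation -----

    def validate(self) -> "ModelParameters":
        def _all(cond) -> bool:
            return bool(np.all(cond))

        for name in _PROB_FIELDS + _UTILITY_FIELDS:
            v = getattr(self, name)
            if not _all((np.asarray(v) >= 0.0) & (np.asarray(v) <= 1.0)):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in _RR_FIELDS:
            if not _all(np.asarray(getattr(self, name)) > 0.0):
                raise ValidationError(f"{name} must be positive")
        for name in _COST_FIELDS:
            if not _all(np.asarray(getattr(self, name)) >= 0.0):
                raise ValidationError(f"{name} must be non-negative")
        for pair, total in (
            (("p_fx_major", "p_fx_minor"), self.p_fx_major + self.p_fx_minor),
            (("p_inj_major", "p_inj_minor"), self.p_inj_major + self.p_inj_minor),
        ):
            if not _all(np.abs(np.asarray(total) - 1.0) <= 1e-9):
                raise ValidationError(f"{pair[0]} + {pair[1]} must equal 1")
        for band in FALL_DEATH_BANDS:
            if band not in self.p_death_fall_by_age:
                raise ValidationError(f"p_death_fall_by_age missing band {band}")
            v = np.asarray(self.p_death_fall_by_age[band])
            if not _all((v >= 0.0) & (v <= 1.0)):
                raise ValidationError(f"p_death_fall_by_age[{band}] must lie in [0, 1]")
        for age, q in self.background_mortality.items():
            if not (isinstance(age, int) and 0.0 <= q <= 1.0):
                raise ValidationError(f"background_mortality[{age!r}] invalid")
        if self.horizon_years <= 0:
            raise ValidationError("horizon_years must be positive")
        if self.cycle_months <= 0 or (self.horizon_years * 12) % self.cycle_months != 0:
            raise ValidationError(
                "horizon_years * 12 must be divisible by cycle_months"
            )
        if not 0.0 <= self.discount_annual:
            raise ValidationError("discount_annual must be non-negative")
        if not self.wtp >= 0.0:
            raise ValidationError("wtp must be non-negative")
        return self

    def replace(self, **overrides) -> "ModelParameters":
        """Return a validated copy with the given fields replaced.

        Fall-death bands may be addressed as ``p_death_fall_60_64`` etc.
        """
        bands = {}
        plain = {}
        for key, value in overrides.items():
            if key.startswith("p_death_fall_"):
                band = key[len("p_death_fall_"):]
                if band not in FALL_DEATH_BANDS:
                    raise ValidationError(f"unknown fall-death band in {key!r}")
                bands[band] = value
            elif (
                key in VALUE_FIELDS
                or key in _SETTING_FIELDS
                or key in ("background_mortality", "p_death_fall_by_age")
            ):
                plain[key] = value
            else:
                raise ValidationError(f"unknown parameter {key!r}")
        if bands:
            plain["p_death_fall_by_age"] = {**self.p_death_fall_by_age, **bands}
        if "c_intervention" in plain:
            # the costed line items describe the default delivery model only
            plain["intervention_cost_components"] = None
        return dataclasses.replace(self, **plain).validate()


def _scalar_mean(v) -> float:
    return float(np.mean(np.asarray(v, dtype=float)))


@dataclass(frozen=True)
class ScenarioOverride:
    """A named scenario: parameter overrides applied to a base input set."""

    name: str
    overrides: Mapping[str, float]

    def apply(self, params: ModelParameters) -> ModelParameters:
        return params.replace(**dict(self.overrides))


def intervention_cost_total(components: Mapping[str, float]) -> float:
    """Total per-participant intervention cost from its costed line items."""
    return sum(components.values())


# --------------------------------------------------------------------------
# configuration I/O


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("fallscea") / "data" / name)


def read_background_mortality(path: Union[str, Path, None] = None) -> Dict[int, float]:
    """Read an ``age,annual_death_probability`` CSV (packaged default if None)."""
    path = _data_path("background_mortality.csv") if path is None else Path(path)
    table: Dict[int, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[int(row["age"])] = float(row["annual_death_probability"])
    if not table:
        raise ConfigError(f"background mortality table {path} is empty")
    return table


_ESTIMATE_KEYS = {"mean", "ci_low", "ci_high", "family", "units", "source"}
_TOP_LEVEL_KEYS = {
    "settings",
    "parameters",
    "intervention_cost_components",
    "background_mortality_file",
    "background_mortality",
}


def load_parameters(
    source: Union[str, Path, Mapping, None] = None,
) -> ModelParameters:
    """Load and validate a model configuration.

    ``source`` may be None (packaged defaults), a path to a YAML file, or
    an already-parsed mapping.  Unknown keys are rejected by name.
    """
    base_dir: Optional[Path] = None
    if source is None:
        source = _data_path("default_parameters.yaml")
    if isinstance(source, (str, Path)):
        base_dir = Path(source).parent
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration document must be a mapping")

    unknown = set(doc) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")

    kwargs: Dict[str, object] = {}
    settings = doc.get("settings", {})
    bad = set(settings) - set(_SETTING_FIELDS)
    if bad:
        raise ConfigError(f"unknown settings keys: {sorted(bad)}")
    kwargs.update(settings)

    estimates: Dict[str, ParameterEstimate] = {}
    death_bands: Dict[str, float] = {}
    params_doc = doc.get("parameters", {})
    known_names = set(VALUE_FIELDS) | {f"p_death_fall_{b}" for b in FALL_DEATH_BANDS}
    for name, entry in params_doc.items():
        if name not in known_names:
            raise ConfigError(f"unknown parameter {name!r}")
        if isinstance(entry, Mapping):
            bad = set(entry) - _ESTIMATE_KEYS
            if bad:
                raise ConfigError(f"parameter {name!r}: unknown keys {sorted(bad)}")
            missing = {"mean", "ci_low", "ci_high", "family"} - set(entry)
            if missing:
                raise ConfigError(f"parameter {name!r}: missing {sorted(missing)}")
            est = ParameterEstimate(name=name, **{k: entry[k] for k in _ESTIMATE_KEYS if k in entry})
            estimates[name] = est
            value = float(est.mean)
        else:
            value = float(entry)  # bare number: fixed value, no PSA distribution
        if name.startswith("p_death_fall_"):
            death_bands[name[len("p_death_fall_"):]] = value
        else:
            kwargs[name] = value

    # a config that declares a parameters section must cover every value field
    required = set(VALUE_FIELDS) - set(kwargs)
    if params_doc and required:
        raise ConfigError(f"incomplete config: missing parameters {sorted(required)}")
    missing_bands = set(FALL_DEATH_BANDS) - set(death_bands)
    if params_doc and missing_bands:
        raise ConfigError(f"incomplete config: missing fall-death bands {sorted(missing_bands)}")
    if death_bands:
        kwargs["p_death_fall_by_age"] = death_bands

    if "background_mortality" in doc:
        kwargs["background_mortality"] = {
            int(k): float(v) for k, v in doc["background_mortality"].items()
        }
    else:
        bg_file = doc.get("background_mortality_file")
        if bg_file is not None and base_dir is not None and (base_dir / bg_file).exists():
            kwargs["background_mortality"] = read_background_mortality(base_dir / bg_file)
        else:
            kwargs["background_mortality"] = read_background_mortality()

    components = doc.get("intervention_cost_components")
    if components is not None:
        components = {k: float(v) for k, v in components.items()}
        total = sum(components.values())
        declared = kwargs.get("c_intervention")
        if declared is not None and abs(total - float(declared)) > 0.5:
            raise ConfigError(
                f"intervention cost components sum to {total}, "
                f"but c_intervention is {declared}"
            )
        kwargs["intervention_cost_components"] = components

    kwargs["estimates"] = estimates
    try:
        return ModelParameters(**kwargs).validate()
    except TypeError as exc:  # unexpected constructor keys
        raise ConfigError(str(exc)) from exc


def dump_parameters(params: ModelParameters, path: Union[str, Path]) -> None:
    """Serialise a parameter set to YAML; ``load_parameters`` round-trips it."""
    doc: Dict[str, object] = {
        "settings": {
            "start_age": params.start_age,
            "horizon_years": params.horizon_years,
            "cycle_months": params.cycle_months,
            "discount_annual": params.discount_annual,
            "wtp": params.wtp,
        }
    }
    pdoc: Dict[str, object] = {}
    for name in VALUE_FIELDS:
        value = getattr(params, name)
        est = params.estimates.get(name)
        if est is not None:
            pdoc[name] = {
                "mean": est.mean,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "family": est.family,
                "units": est.units,
                "source": est.source,
            }
        else:
            pdoc[name] = float(value)
    for band in FALL_DEATH_BANDS:
        name = f"p_death_fall_{band}"
        est = params.estimates.get(name)
        if est is not None:
            pdoc[name] = {
                "mean": est.mean,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "family": est.family,
                "units": est.units,
                "source": est.source,
            }
        else:
            pdoc[name] = float(params.p_death_fall_by_age[band])
    doc["parameters"] = pdoc
    doc["background_mortality"] = {
        int(k): float(v) for k, v in sorted(params.background_mortality.items())
    }
    if params.intervention_cost_components is not None:
        doc["intervention_cost_components"] = dict(params.intervention_cost_components)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
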