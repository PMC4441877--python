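"""Typed, validated inputs for the SPG-stimulation cost-utility model.

Every model input — clinical effectiveness, costs, utilities, discounting,
horizon — lives in one frozen :class:`ModelParams` tree.  Values are 2014
euros, EQ-5D index utilities, and times in years unless a field name says
otherwise.  The shipped base case encodes the German-payer analysis the
package reproduces; :func:`load_params` reads the same structure from a
YAML document, merging partial configurations over the base case.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Any, Mapping

import yaml

#: Length of a model year in days (the calendar mean; cycle arithmetic and
#: per-attack cost annualisation both use it).
DAYS_PER_YEAR = 365.25

#: Lowest value of the EQ-5D index under the German value set ("worse than
#: dead" states); utilities must lie in [EQ5D_FLOOR, 1].
EQ5D_FLOOR = -0.594

_TIMINGS = ("start", "midpoint", "end", "continuous")
_EXTRAPOLATION_RULES = ("year2-average", "hold-last")


class ParamError(ValueError):
    """A configuration value violates a model invariant.

    The message starts with the dotted key path of the offending value.
    """


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ParamError(f"{key}: {msg}")


def _check_prob(value: float, key: str) -> None:
    _check(0.0 <= value <= 1.0, key, f"must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ClinicalParams:
    """Clinical effectiveness of stimulation relative to the baseline period.

    ``annual_decline_fraction`` is the *relative* share of the initial
    prophylactic effect lost per model year (0.10 of a 31 % reduction is an
    absolute 3.1 percentage points per year), so scenarios that rescale the
    initial effect scale the decline with it.
    """

    baseline_attacks_per_day: float
    pain_relief_prob: float
    initial_freq_reduction: float
    annual_decline_fraction: float

    def __post_init__(self) -> None:
        _check(self.baseline_attacks_per_day > 0, "baseline_attacks_per_day",
               f"must be > 0, got {self.baseline_attacks_per_day!r}")
        _check_prob(self.pain_relief_prob, "pain_relief_prob")
        _check_prob(self.initial_freq_reduction, "initial_freq_reduction")
        _check_prob(self.annual_decline_fraction, "annual_decline_fraction")


@dataclass(frozen=True)
class CostParams:
    """Direct medical costs (2014 euros, statutory-health-insurance payer view).

    Up-front stimulation costs are expectation-weighted by the trial
    complication frequencies (revision 4/32, surgical-site infection 3/32,
    explant 2/32).  ``revision_device_paid_by_payer`` is False in the base
    case because the manufacturer replaces the device in revisions at no
    charge; a sensitivity scenario flips it.
    """

    med_cost_per_attack: float
    implant_drg: float
    device_cost: float
    imaging_cost: float
    titration_visits_cost: float
    revision_drg: float
    revision_prob: float
    revision_device_paid_by_payer: bool
    antibiotics_cost: float
    infection_prob: float
    explant_cost: float
    explant_prob: float

    _MONEY = ("med_cost_per_attack", "implant_drg", "device_cost", "imaging_cost",
              "titration_visits_cost", "revision_drg", "antibiotics_cost", "explant_cost")

    def __post_init__(self) -> None:
        for name in self._MONEY:
            value = getattr(self, name)
            _check(value >= 0, name, f"money amounts must be >= 0, got {value!r}")
        for name in ("revision_prob", "infection_prob", "explant_prob"):
            _check_prob(getattr(self, name), name)


@dataclass(frozen=True)
class UtilityParams:
    """EQ-5D utility inputs for both arms.

    ``spg_utility_points`` is the mapped utility trajectory of the
    stimulation arm as ``(months since implant, utility)`` pairs;
    ``annual_qaly_gain`` is the calibrated per-year undiscounted QALY gain
    over the constant-baseline control arm (years past the end of the list
    reuse its last entry).  ``extrapolation_rule`` governs the interpolated
    utility path beyond the last observed point: constant at the year-2
    time-average (default) or held at the last observation.
    """

    baseline_utility: float
    spg_utility_points: tuple[tuple[float, float], ...]
    annual_qaly_gain: tuple[float, ...]
    extrapolation_rule: str = "year2-average"

    def __post_init__(self) -> None:
        object.__setattr__(self, "spg_utility_points",
                           tuple((float(t), float(u)) for t, u in self.spg_utility_points))
        object.__setattr__(self, "annual_qaly_gain",
                           tuple(float(g) for g in self.annual_qaly_gain))
        _check(EQ5D_FLOOR <= self.baseline_utility <= 1.0, "baseline_utility",
               f"must be an EQ-5D index in [{EQ5D_FLOOR}, 1], got {self.baseline_utility!r}")
        _check(len(self.spg_utility_points) >= 1, "spg_utility_points",
               "at least one (months, utility) point is required")
        months = [t for t, _ in self.spg_utility_points]
        _check(all(b > a for a, b in zip(months, months[1:])), "spg_utility_points",
               "time points must be strictly increasing")
        for _, u in self.spg_utility_points:
            _check(EQ5D_FLOOR <= u <= 1.0, "spg_utility_points",
                   f"utilities must lie in [{EQ5D_FLOOR}, 1], got {u!r}")
        _check(len(self.annual_qaly_gain) >= 1, "annual_qaly_gain",
               "at least one per-year gain is required")
        _check(self.extrapolation_rule in _EXTRAPOLATION_RULES, "extrapolation_rule",
               f"must be one of {_EXTRAPOLATION_RULES}, got {self.extrapolation_rule!r}")


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting convention.

    Flows accrue uniformly over cycles of ``cycle_length_days`` and each
    cycle's flow is discounted at a single point chosen by ``timing``
    (``"start"``, ``"midpoint"``, ``"end"``) or exactly integrated
    (``"continuous"``).  ``stim_med_timing`` applies to the stimulation
    arm's residual-medication stream only; its default (``"midpoint"``,
    against ``"end"`` for everything else) is the calibration that
    reproduces the published five-year arm totals — see docs/methods.md.
    Set both timings equal for a uniform convention, or
    ``cycle_length_days = 365.25`` with ``timing = "start"`` for classic
    annual-start discounting.
    """

    annual_rate: float
    cycle_length_days: float = 28.0
    timing: str = "end"
    stim_med_timing: str = "midpoint"

    def __post_init__(self) -> None:
        _check(self.annual_rate >= 0, "annual_rate",
               f"must be >= 0, got {self.annual_rate!r}")
        _check(self.cycle_length_days > 0, "cycle_length_days",
               f"must be > 0, got {self.cycle_length_days!r}")
        for name in ("timing", "stim_med_timing"):
            _check(getattr(self, name) in _TIMINGS, name,
                   f"must be one of {_TIMINGS}, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class ModelParams:
    """Complete input set for one model run."""

    clinical: ClinicalParams
    costs: CostParams
    utility: UtilityParams
    discount: DiscountSpec
    horizon_years: float

    def __post_init__(self) -> None:
        _check(self.horizon_years > 0, "horizon_years",
               f"must be > 0, got {self.horizon_years!r}")


_SECTIONS: dict[str, type | None] = {
    "clinical": ClinicalParams,
    "costs": CostParams,
    "utility": UtilityParams,
    "discount": DiscountSpec,
    "horizon_years": None,
}


def _build_section(name: str, cls: type, mapping: Mapping[str, Any]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ParamError(f"{name}.{sorted(unknown)[0]}: unknown key")
    required = {f.name for f in fields.values()
                if f.default is dataclasses.MISSING
                and f.default_factory is dataclasses.MISSING}
    missing = required - set(mapping)
    if missing:
        raise ParamError(f"{name}.{sorted(missing)[0]}: missing required key")
    try:
        return cls(**mapping)
    except ParamError as err:
        raise ParamError(f"{name}.{err}") from None


def _deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), Mapping):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def _params_from_mapping(config: Mapping[str, Any]) -> ModelParams:
    unknown = set(config) - set(_SECTIONS)
    if unknown:
        raise ParamError(f"{sorted(unknown)[0]}: unknown key")
    missing = set(_SECTIONS) - set(config)
    if missing:
        raise ParamError(f"{sorted(missing)[0]}: missing required key")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        value = config[name]
        if cls is None:
            kwargs[name] = value
        else:
            if not isinstance(value, Mapping):
                raise ParamError(f"{name}: expected a mapping, got {type(value).__name__}")
            kwargs[name] = _build_section(name, cls, value)
    return ModelParams(**kwargs)


def _base_case_mapping() -> dict[str, Any]:
    text = resources.files("spgcea.data").joinpath("base_case.yaml").read_text()
    return yaml.safe_load(text)


def load_params(config_text: str, merge_defaults: bool = True) -> ModelParams:
    """Parse a YAML configuration into a validated :class:`ModelParams`.

    Partial documents are merged over the shipped base case when
    ``merge_defaults`` is true; unknown keys are rejected either way, and
    every invariant violation is reported with its dotted key path.
    """
    try:
        config = yaml.safe_load(config_text)
    except yaml.YAMLError as err:
        raise ParamError(f"configuration does not parse as YAML: {err}") from err
    if config is None:
        config = {}
    if not isinstance(config, Mapping):
        raise ParamError(f"top level must be a mapping, got {type(config).__name__}")
    if merge_defaults:
        config = _deep_merge(_base_case_mapping(), config)
    return _params_from_mapping(config)


def serialize_params(params: ModelParams) -> str:
    """Render parameters back to canonical YAML (inverse of :func:`load_params`)."""
    raw = dataclasses.asdict(params)
    raw["utility"]["spg_utility_points"] = [
        [t, u] for t, u in raw["utility"]["spg_utility_points"]]
    raw["utility"]["annual_qaly_gain"] = list(raw["utility"]["annual_qaly_gain"])
    return yaml.safe_dump(raw, sort_keys=True)


@lru_cache(maxsize=1)
def default_params() -> ModelParams:
    """The base-case parameter set (5-year horizon, 3 %/yr discounting)."""
    return _params_from_mapping(_base_case_mapping())


def apply_overrides(params: ModelParams, overrides: Mapping[str, Any]) -> ModelParams:
    """Return a copy of ``params`` with dotted-path overrides applied.

    Paths name either a top-level field (``"horizon_years"``) or a nested
    one (``"clinical.pain_relief_prob"``).  The returned tree is re-validated,
    so an override violating an invariant raises :class:`ParamError`.
    """
    sections: dict[str, dict[str, Any]] = {}
    top: dict[str, Any] = {}
    for path, value in overrides.items():
        parts = path.split(".")
        if len(parts) == 1:
            if parts[0] not in _SECTIONS or _SECTIONS[parts[0]] is not None:
                raise ParamError(f"{path}: unknown override path")
            top[parts[0]] = value
        elif len(parts) == 2:
            section, field = parts
            cls = _SECTIONS.get(section)
            if cls is None:
                raise ParamError(f"{path}: unknown override path")
            if field not in {f.name for f in dataclasses.fields(cls)}:
                raise ParamError(f"{path}: unknown override path")
            sections.setdefault(section, {})[field] = value
        else:
            raise ParamError(f"{path}: unknown override path")
    kwargs: dict[str, Any] = dict(top)
    for section, fields in sections.items():
        try:
            kwargs[section] = dataclasses.replace(getattr(params, section), **fields)
        except ParamError as err:
            raise ParamError(f"{section}.{err}") from None
    return dataclasses.replace(params, **kwargs)
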