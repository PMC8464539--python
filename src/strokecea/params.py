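"""Model parameterization: health-state distributions, clinical probabilities,
costs, utilities, and analysis settings.

The parameter set describes a cohort of suspected ischemic stroke patients
receiving CTA, the fraction with a large vessel occlusion (LVO), treatment
eligibility and detection rates, per-mRS-state costs and utility weights, and
the discounting conventions of the lifetime model.  A single :class:`ModelParams`
object is the source of truth for one model run; defaults are the published
base case of the analysis this package implements.

Config files are flat YAML (JSON also parses), keyed exactly by the field
names below.  Unknown keys are rejected so parameter-name typos cannot
silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MrsDistribution",
    "ClinicalParams",
    "CostParams",
    "UtilityParams",
    "AnalysisSettings",
    "ModelParams",
    "ConfigError",
    "load_config",
    "save_config",
    "params_to_dict",
    "params_from_dict",
    "validate_params",
    "convert_currency",
    "N_STATES",
    "DEATH",
]

N_STATES = 7  # mRS 0..5 plus death
DEATH = 6

# How far an input vector may deviate from summing to 1 and still be accepted
# (then renormalized).  Printed rounded percentages must load; grossly
# inconsistent vectors must not.
_SUM_TOLERANCE = 0.005


class ConfigError(ValueError):
    """Raised for unparsable or invalid configuration input."""


@dataclass(frozen=True)
class MrsDistribution:
    """Probability distribution over mRS 0-5 and death (mRS 6).

    The constructor accepts entries whose sum deviates from 1 by at most 0.5%
    and renormalizes them to sum exactly to 1; anything further off is
    rejected as inconsistent input.
    """

    probs: tuple[float, ...]

    def __init__(self, probs: Sequence[float]):
        p = np.asarray(probs, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError(
                f"mRS distribution needs {N_STATES} entries (mRS 0-5 and death), got {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"mRS probabilities must lie in [0, 1], got {p.tolist()}")
        total = float(p.sum())
        if abs(total - 1.0) > _SUM_TOLERANCE:
            raise ValueError(
                f"mRS probabilities sum to {total:.6f}; must be within 0.5% of 1"
            )
        object.__setattr__(self, "probs", tuple(float(x) for x in p / total))

    def as_array(self) -> np.ndarray:
        return np.array(self.probs, dtype=float)

    @classmethod
    def point_mass(cls, state: int) -> "MrsDistribution":
        p = np.zeros(N_STATES)
        p[state] = 1.0
        return cls(p)

    @property
    def p_death(self) -> float:
        return self.probs[DEATH]

    @property
    def alive(self) -> np.ndarray:
        """Probability mass on the six alive states."""
        return self.as_array()[:DEATH]


# 90-day mRS outcome distributions for LVO patients, pooled from large
# randomized thrombectomy trials: with intra-arterial treatment (IAT) and
# without.
_MRS_IAT = (0.11, 0.18, 0.20, 0.17, 0.16, 0.04, 0.14)
_MRS_NO_IAT = (0.05, 0.08, 0.11, 0.17, 0.27, 0.12, 0.20)


@dataclass(frozen=True)
class ClinicalParams:
    """Clinical probabilities and cohort description.

    p_lvo
        Prevalence of LVO among CTA-receiving suspected-stroke patients.
    p_eligible
        Fraction of LVO patients eligible for IAT.
    p_missed
        Fraction of LVOs missed under standard-of-care reading.
    reduction
        Fraction of those misses recovered when readers are AI-aided.
    p_recurrent
        Annual probability of recurrent stroke after the acute phase.
    age0, cohort_n
        Cohort starting age (years) and yearly cohort size.
    """

    p_lvo: float = 0.306
    p_eligible: float = 0.438
    p_missed: float = 0.06
    reduction: float = 0.50
    p_recurrent: float = 0.0284
    age0: int = 66
    cohort_n: int = 71_840
    mrs_iat: MrsDistribution = field(default_factory=lambda: MrsDistribution(_MRS_IAT))
    mrs_no_iat: MrsDistribution = field(
        default_factory=lambda: MrsDistribution(_MRS_NO_IAT)
    )


@dataclass(frozen=True)
class CostParams:
    """Costs in 2019 US dollars.

    ``acute_by_state`` covers the first 90 days per mRS state 0-6 (death
    included: terminal-care cost); ``longterm_by_state`` is the annual cost
    per alive mRS state.  ``tx_iat``/``tx_no_iat`` are blended average
    treatment costs for IAT-eligible and non-eligible patients.
    ``ai_per_analysis`` is the software fee charged once per CTA analysis.
    ``fp_cost_per_point`` x ``fp_rate_points`` is an optional linear surcharge
    for extra reading time caused by software false positives.
    """

    acute_by_state: tuple[float, ...] = (4350, 5117, 5885, 22_695, 30_704, 36_468, 4603)
    longterm_by_state: tuple[float, ...] = (3936, 4631, 5325, 18_944, 25_631, 41_621)
    tx_iat: float = 11_728.0
    tx_no_iat: float = 1004.0
    ai_per_analysis: float = 40.0
    discount_costs: float = 0.04
    fp_cost_per_point: float = 0.0
    fp_rate_points: float = 0.0


@dataclass(frozen=True)
class UtilityParams:
    """Utility weight per alive mRS state (death contributes 0) and the
    annual utility discount rate."""

    utility_by_state: tuple[float, ...] = (0.95, 0.93, 0.83, 0.62, 0.42, 0.11)
    discount_utilities: float = 0.015


@dataclass(frozen=True)
class AnalysisSettings:
    """Run-level switches.

    cycles
        Number of yearly Markov cycles after the acute phase.
    wtp_per_qaly
        Willingness-to-pay reference value for one QALY (USD).
    acute_year_fraction
        Fraction of a year over which acute-phase utility accrues
        (90 days by default; set to 0 to ignore acute-phase QALYs).
    non_lvo_profile
        Outcome profile of patients without an LVO: ``healthy`` (mRS 0
        utility, no stroke costs, background mortality only), ``non_iat``
        (treated like untreated stroke patients) or ``custom``
        (``custom_profile`` must then be supplied).
    recurrence_rule
        How recurrent-stroke outcomes are redistributed, under the
        constraint that recurrence cannot improve the mRS state:
        ``clamp_max`` (new state = max(current, draw from the no-IAT
        distribution)) or ``truncate_renormalize`` (draw from the no-IAT
        distribution restricted to states >= current, renormalized).
    recurrence_acute_costs
        Whether a recurrent stroke re-triggers the acute per-state cost in
        the cycle it occurs.
    """

    cycles: int = 70
    wtp_per_qaly: float = 25_662.0
    acute_year_fraction: float = 90 / 365.25
    non_lvo_profile: str = "healthy"
    custom_profile: MrsDistribution | None = None
    recurrence_rule: str = "clamp_max"
    recurrence_acute_costs: bool = False
    seed: int = 0


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of one model run."""

    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def defaults(cls) -> "ModelParams":
        return cls()


def convert_currency(amount_gbp: float, rate: float) -> float:
    """Convert an amount at a given exchange rate (e.g. 2019 GBP->USD 1.283)."""
    if amount_gbp < 0:
        raise ValueError("amount must be non-negative")
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_gbp * rate


# ---------------------------------------------------------------------------
# Validation

def _check_prob(violations: list[str], name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        violations.append(f"{name} must lie in [0, 1], got {value}")


def validate_params(params: ModelParams) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    v: list[str] = []
    c = params.clinical
    for name in ("p_lvo", "p_eligible", "p_missed", "reduction", "p_recurrent"):
        _check_prob(v, name, getattr(c, name))
    if not (isinstance(c.age0, (int, np.integer)) and c.age0 >= 18):
        v.append(f"age0 must be an integer >= 18, got {c.age0!r}")
    if not (isinstance(c.cohort_n, (int, np.integer)) and c.cohort_n > 0):
        v.append(f"cohort_n must be a positive integer, got {c.cohort_n!r}")
    for dist_name in ("mrs_iat", "mrs_no_iat"):
        dist = getattr(c, dist_name)
        if abs(sum(dist.probs) - 1.0) > 1e-9:
            v.append(f"{dist_name} probabilities must sum to 1")

    k = params.costs
    if len(k.acute_by_state) != N_STATES:
        v.append(f"acute_by_state needs {N_STATES} entries, got {len(k.acute_by_state)}")
    if len(k.longterm_by_state) != DEATH:
        v.append(f"longterm_by_state needs {DEATH} entries, got {len(k.longterm_by_state)}")
    for name in ("tx_iat", "tx_no_iat", "ai_per_analysis", "fp_cost_per_point", "fp_rate_points"):
        if getattr(k, name) < 0:
            v.append(f"{name} must be non-negative, got {getattr(k, name)}")
    for name, vec in (("acute_by_state", k.acute_by_state), ("longterm_by_state", k.longterm_by_state)):
        if any(x < 0 for x in vec):
            v.append(f"{name} entries must be non-negative")
    if not 0.0 <= k.discount_costs <= 0.2:
        v.append(f"discount_costs must lie in [0, 0.2], got {k.discount_costs}")

    u = params.utilities
    if len(u.utility_by_state) != DEATH:
        v.append(f"utility_by_state needs {DEATH} entries, got {len(u.utility_by_state)}")
    else:
        if any(not 0.0 <= x <= 1.0 for x in u.utility_by_state):
            v.append("utility_by_state entries must lie in [0, 1]")
        if any(
            u.utility_by_state[i] < u.utility_by_state[i + 1]
            for i in range(len(u.utility_by_state) - 1)
        ):
            v.append("utility_by_state must be non-increasing from mRS 0 to mRS 5")
    if not 0.0 <= u.discount_utilities <= 0.2:
        v.append(f"discount_utilities must lie in [0, 0.2], got {u.discount_utilities}")

    s = params.settings
    if s.cycles < 1:
        v.append(f"cycles must be >= 1, got {s.cycles}")
    if not 0.0 <= s.acute_year_fraction <= 1.0:
        v.append(f"acute_year_fraction must lie in [0, 1], got {s.acute_year_fraction}")
    if s.wtp_per_qaly < 0:
        v.append(f"wtp_per_qaly must be non-negative, got {s.wtp_per_qaly}")
    if s.non_lvo_profile not in ("healthy", "non_iat", "custom"):
        v.append(f"non_lvo_profile must be healthy|non_iat|custom, got {s.non_lvo_profile!r}")
    if s.non_lvo_profile == "custom" and s.custom_profile is None:
        v.append("non_lvo_profile is 'custom' but custom_profile is not set")
    if s.recurrence_rule not in ("clamp_max", "truncate_renormalize"):
        v.append(
            f"recurrence_rule must be clamp_max|truncate_renormalize, got {s.recurrence_rule!r}"
        )
    return v


# ---------------------------------------------------------------------------
# Flat config schema: key -> (section attribute, field name)

_SCHEMA: dict[str, tuple[str, str]] = {
    # clinical
    "p_lvo": ("clinical", "p_lvo"),
    "p_eligible": ("clinical", "p_eligible"),
    "p_missed": ("clinical", "p_missed"),
    "reduction": ("clinical", "reduction"),
    "p_recurrent": ("clinical", "p_recurrent"),
    "age0": ("clinical", "age0"),
    "cohort_n": ("clinical", "cohort_n"),
    "mrs_iat": ("clinical", "mrs_iat"),
    "mrs_no_iat": ("clinical", "mrs_no_iat"),
    # costs
    "acute_by_state": ("costs", "acute_by_state"),
    "longterm_by_state": ("costs", "longterm_by_state"),
    "tx_iat": ("costs", "tx_iat"),
    "tx_no_iat": ("costs", "tx_no_iat"),
    "ai_per_analysis": ("costs", "ai_per_analysis"),
    "discount_costs": ("costs", "discount_costs"),
    "fp_cost_per_point": ("costs", "fp_cost_per_point"),
    "fp_rate_points": ("costs", "fp_rate_points"),
    # utilities
    "utility_by_state": ("utilities", "utility_by_state"),
    "discount_utilities": ("utilities", "discount_utilities"),
    # settings
    "cycles": ("settings", "cycles"),
    "wtp_per_qaly": ("settings", "wtp_per_qaly"),
    "acute_year_fraction": ("settings", "acute_year_fraction"),
    "non_lvo_profile": ("settings", "non_lvo_profile"),
    "custom_profile": ("settings", "custom_profile"),
    "recurrence_rule": ("settings", "recurrence_rule"),
    "recurrence_acute_costs": ("settings", "recurrence_acute_costs"),
    "seed": ("settings", "seed"),
}

_DIST_KEYS = {"mrs_iat", "mrs_no_iat", "custom_profile"}
_TUPLE_KEYS = {"acute_by_state", "longterm_by_state", "utility_by_state"}
_INT_KEYS = {"age0", "cohort_n", "cycles", "seed"}


def params_from_dict(flat: dict) -> ModelParams:
    """Build a validated :class:`ModelParams` from a flat key->value mapping.

    Omitted keys take the published base-case defaults; unknown keys raise
    :class:`ConfigError`.
    """
    unknown = sorted(set(flat) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")

    sections: dict[str, dict] = {"clinical": {}, "costs": {}, "utilities": {}, "settings": {}}
    for key, value in flat.items():
        section, attr = _SCHEMA[key]
        try:
            if key in _DIST_KEYS:
                value = None if value is None else MrsDistribution(value)
            elif key in _TUPLE_KEYS:
                value = tuple(float(x) for x in value)
            elif key in _INT_KEYS:
                if float(value) != int(value):
                    raise ValueError(f"expected an integer, got {value!r}")
                value = int(value)
            elif key == "recurrence_acute_costs":
                value = bool(value)
            elif key in ("non_lvo_profile", "recurrence_rule"):
                value = str(value)
            else:
                value = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r}: {exc}") from exc
        sections[section][attr] = value

    params = ModelParams(
        clinical=ClinicalParams(**sections["clinical"]),
        costs=CostParams(**sections["costs"]),
        utilities=UtilityParams(**sections["utilities"]),
        settings=AnalysisSettings(**sections["settings"]),
    )
    violations = validate_params(params)
    if violations:
        raise ConfigError("invalid parameters:\n  " + "\n  ".join(violations))
    return params


def params_to_dict(params: ModelParams) -> dict:
    """Flatten a ModelParams into the config-schema mapping (round-trips)."""
    flat: dict = {}
    for key, (section, attr) in _SCHEMA.items():
        value = getattr(getattr(params, section), attr)
        if isinstance(value, MrsDistribution):
            value = [float(x) for x in value.probs]
        elif isinstance(value, tuple):
            value = [float(x) for x in value]
        elif value is None:
            continue
        flat[key] = value
    return flat


def load_config(path) -> ModelParams:
    """Load a YAML/JSON config file; omitted fields take the base-case defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(raw).__name__}")
    return params_from_dict(raw)


def save_config(params: ModelParams, path) -> None:
    """Write the full flat parameter set as YAML (loadable by load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=True)
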