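"""Acute-phase decision tree (first 90 days).

Each suspected-stroke patient receiving CTA either has a large vessel
occlusion (LVO) or not.  LVO patients are detected or missed by the reader;
detected, IAT-eligible patients receive intra-arterial thrombectomy and take
the treated 90-day mRS outcome distribution, everyone else with an LVO takes
the untreated one.  The AI-aided strategy differs from usual care only in the
detection rate (a fraction of misses is recovered) and in a per-analysis
software fee charged for every CTA patient.

Missed-but-eligible patients are the only mass the strategies disagree on:
missed-ineligible and detected-ineligible patients are outcome-identical (no
IAT either way), so the tree collapses to the detection x eligibility product.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .params import DEATH, N_STATES, ModelParams, MrsDistribution

__all__ = [
    "Strategy",
    "AcuteResult",
    "detection_rate",
    "iat_fraction",
    "expected_over_states",
    "non_lvo_distribution",
    "lvo_mrs_at_90",
    "mrs_at_90",
    "acute_outcomes",
    "incremental_acute",
]


class Strategy(str, enum.Enum):
    usual_care = "usual_care"
    ai_aided = "ai_aided"


@dataclass(frozen=True)
class AcuteResult:
    """Per-strategy acute-phase summary.

    cost_pp / qaly_pp are expectations per cohort patient over the first 90
    days (undiscounted); dist90 is the whole-cohort mRS distribution at day
    90 that seeds the lifetime model; f_iat the fraction of the cohort
    receiving IAT.
    """

    cost_pp: float
    qaly_pp: float
    dist90: MrsDistribution
    f_iat: float


def detection_rate(strategy: Strategy, p_missed: float, reduction: float) -> float:
    """Probability that an LVO is detected under the given strategy.

    Usual care misses a fraction ``p_missed``; the AI-aided reader recovers
    a fraction ``reduction`` of those misses.
    """
    for name, x in (("p_missed", p_missed), ("reduction", reduction)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    if Strategy(strategy) is Strategy.usual_care:
        return 1.0 - p_missed
    return 1.0 - p_missed * (1.0 - reduction)


def iat_fraction(params: ModelParams, strategy: Strategy) -> float:
    """Fraction of the whole cohort treated with IAT: only detected,
    eligible LVO patients are treated."""
    c = params.clinical
    return c.p_lvo * c.p_eligible * detection_rate(strategy, c.p_missed, c.reduction)


def expected_over_states(dist: MrsDistribution, values) -> float:
    """Probability-weighted sum of a per-state value vector.

    Accepts 7 values (mRS 0-5 + death) or 6 (alive states only; death then
    contributes zero, the QALY convention).
    """
    v = np.asarray(values, dtype=float)
    p = dist.as_array()
    if v.shape == (N_STATES,):
        return float(p @ v)
    if v.shape == (DEATH,):
        return float(p[:DEATH] @ v)
    raise ValueError(f"need {DEATH} or {N_STATES} per-state values, got shape {v.shape}")


def non_lvo_distribution(params: ModelParams) -> MrsDistribution:
    """90-day mRS distribution assigned to patients without an LVO."""
    profile = params.settings.non_lvo_profile
    if profile == "healthy":
        return MrsDistribution.point_mass(0)
    if profile == "non_iat":
        return params.clinical.mrs_no_iat
    if profile == "custom":
        if params.settings.custom_profile is None:
            raise ValueError("non_lvo_profile is 'custom' but no custom_profile was supplied")
        return params.settings.custom_profile
    raise ValueError(f"unknown non_lvo_profile {profile!r}")


def lvo_mrs_at_90(params: ModelParams, strategy: Strategy) -> MrsDistribution:
    """90-day mRS distribution of the LVO sub-cohort (mixture of treated and
    untreated outcomes weighted by the treated fraction)."""
    c = params.clinical
    if c.p_lvo == 0:
        return c.mrs_no_iat  # vacuous: no LVO mass to weight
    w = iat_fraction(params, strategy) / c.p_lvo
    p = w * c.mrs_iat.as_array() + (1 - w) * c.mrs_no_iat.as_array()
    return MrsDistribution(p)


def mrs_at_90(params: ModelParams, strategy: Strategy) -> MrsDistribution:
    """Whole-cohort mRS distribution at day 90: treated LVO, untreated LVO
    and non-LVO mass mixed in their cohort proportions."""
    c = params.clinical
    f = iat_fraction(params, strategy)
    p = (
        f * c.mrs_iat.as_array()
        + (c.p_lvo - f) * c.mrs_no_iat.as_array()
        + (1 - c.p_lvo) * non_lvo_distribution(params).as_array()
    )
    return MrsDistribution(p)


def acute_outcomes(params: ModelParams, strategy: Strategy) -> AcuteResult:
    """Expected acute-phase (90-day) cost and QALYs per cohort patient.

    Costs: blended treatment cost for the treated and untreated LVO mass,
    per-mRS acute management costs for stroke patients (non-LVO patients
    contribute per their configured profile; 'healthy' contributes none),
    the AI fee per analysis in the AI arm, and the optional false-positive
    reading-time surcharge.  The acute phase is undiscounted; utility
    accrues over ``acute_year_fraction`` of a year at the 90-day state.
    """
    strategy = Strategy(strategy)
    c, k, s = params.clinical, params.costs, params.settings
    f = iat_fraction(params, strategy)

    cost = f * k.tx_iat + (c.p_lvo - f) * k.tx_no_iat
    cost += f * expected_over_states(c.mrs_iat, k.acute_by_state)
    cost += (c.p_lvo - f) * expected_over_states(c.mrs_no_iat, k.acute_by_state)
    if s.non_lvo_profile != "healthy":
        cost += (1 - c.p_lvo) * expected_over_states(
            non_lvo_distribution(params), k.acute_by_state
        )
    if strategy is Strategy.ai_aided:
        cost += k.ai_per_analysis
        cost += k.fp_cost_per_point * k.fp_rate_points

    dist90 = mrs_at_90(params, strategy)
    qaly = s.acute_year_fraction * expected_over_states(
        dist90, params.utilities.utility_by_state
    )
    return AcuteResult(cost_pp=cost, qaly_pp=qaly, dist90=dist90, f_iat=f)


def incremental_acute(params: ModelParams) -> tuple[float, float]:
    """Acute-phase incremental (cost, QALYs) per patient, AI minus usual care."""
    ai = acute_outcomes(params, Strategy.ai_aided)
    uc = acute_outcomes(params, Strategy.usual_care)
    return ai.cost_pp - uc.cost_pp, ai.qaly_pp - uc.qaly_pp
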