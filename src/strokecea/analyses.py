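"""Strategy comparison and results machinery.

Couples the acute-phase decision tree to the lifetime Markov model for both
strategies and reports incremental costs and effects (AI-aided minus usual
care) per patient and per yearly cohort, with phase decomposition, net
monetary benefit, dominance, scenario and price grids, threshold (headroom)
pricing and one-way (tornado) sensitivity analysis.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .acute import Strategy, acute_outcomes, mrs_at_90
from .lifetables import MortalityTable
from .markov import run_markov
from .params import (
    AnalysisSettings,
    ClinicalParams,
    CostParams,
    ModelParams,
    UtilityParams,
    validate_params,
)

__all__ = [
    "StrategyOutcome",
    "IncrementalResult",
    "ScenarioCell",
    "TornadoRow",
    "strategy_outcome",
    "compare_strategies",
    "scenario_grid",
    "price_performance_grid",
    "threshold_price",
    "one_way_sensitivity",
    "default_tornado_bounds",
    "population_scale",
    "set_param",
    "base_case_frame",
    "scenario_grid_frame",
    "tornado_frame",
]


@dataclass(frozen=True)
class StrategyOutcome:
    """Absolute expected outcomes of one strategy, per cohort patient."""

    strategy: Strategy
    acute_cost_pp: float
    acute_qaly_pp: float
    longterm_cost_pp: float
    longterm_qaly_pp: float

    @property
    def cost_pp(self) -> float:
        return self.acute_cost_pp + self.longterm_cost_pp

    @property
    def qaly_pp(self) -> float:
        return self.acute_qaly_pp + self.longterm_qaly_pp


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental results, AI-aided minus usual care.

    ``ic_pp``/``ie_pp`` are per-patient incremental cost (USD) and QALYs;
    ``ic_pop``/``ie_pop`` the cohort totals; ``pct_cost``/``pct_qaly`` the
    increments as a percentage of the usual-care absolute totals; ``nmb_pp``
    the net monetary benefit at the configured willingness-to-pay.  The AI
    strategy is *dominant* when it saves costs without losing QALYs; an ICER
    is reported only when it is not dominant and the QALY increment is
    non-zero.  Acute and rest-of-life components sum exactly to the totals.
    """

    ic_pp: float
    ie_pp: float
    ic_pop: float
    ie_pop: float
    pct_cost: float
    pct_qaly: float
    nmb_pp: float
    dominant: bool
    icer: float | None
    acute_ic_pp: float
    acute_ie_pp: float
    longterm_ic_pp: float
    longterm_ie_pp: float
    usual: StrategyOutcome
    ai: StrategyOutcome
    cohort_n: int


@dataclass(frozen=True)
class ScenarioCell:
    p_missed: float
    reduction: float
    ai_cost: float
    ic_pp: float
    ie_pp: float


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low: float
    high: float
    ic_low: float
    ic_high: float
    ie_low: float
    ie_high: float

    @property
    def ic_spread(self) -> float:
        return abs(self.ic_high - self.ic_low)


def _validated(params: ModelParams) -> ModelParams:
    violations = validate_params(params)
    if violations:
        raise ValueError("invalid parameters:\n  " + "\n  ".join(violations))
    return params


def strategy_outcome(
    params: ModelParams, mortality: MortalityTable, strategy: Strategy
) -> StrategyOutcome:
    """Run the decision tree and the Markov model for one strategy."""
    acute = acute_outcomes(params, strategy)
    healthy = (
        1.0 - params.clinical.p_lvo
        if params.settings.non_lvo_profile == "healthy"
        else 0.0
    )
    life = run_markov(acute.dist90, params, mortality, healthy_fraction=healthy)
    return StrategyOutcome(
        strategy=Strategy(strategy),
        acute_cost_pp=acute.cost_pp,
        acute_qaly_pp=acute.qaly_pp,
        longterm_cost_pp=life.cost_pp,
        longterm_qaly_pp=life.qaly_pp,
    )


def compare_strategies(params: ModelParams, mortality: MortalityTable) -> IncrementalResult:
    """Full incremental comparison of the AI-aided strategy against usual care."""
    _validated(params)
    uc = strategy_outcome(params, mortality, Strategy.usual_care)
    ai = strategy_outcome(params, mortality, Strategy.ai_aided)

    acute_ic = ai.acute_cost_pp - uc.acute_cost_pp
    acute_ie = ai.acute_qaly_pp - uc.acute_qaly_pp
    lt_ic = ai.longterm_cost_pp - uc.longterm_cost_pp
    lt_ie = ai.longterm_qaly_pp - uc.longterm_qaly_pp
    ic = acute_ic + lt_ic
    ie = acute_ie + lt_ie

    n = params.clinical.cohort_n
    wtp = params.settings.wtp_per_qaly
    dominant = ic <= 0 and ie >= 0
    icer = None if dominant or ie == 0 else ic / ie
    return IncrementalResult(
        ic_pp=ic,
        ie_pp=ie,
        ic_pop=ic * n,
        ie_pop=ie * n,
        pct_cost=100.0 * ic / uc.cost_pp if uc.cost_pp else float("nan"),
        pct_qaly=100.0 * ie / uc.qaly_pp if uc.qaly_pp else float("nan"),
        nmb_pp=wtp * ie - ic,
        dominant=dominant,
        icer=icer,
        acute_ic_pp=acute_ic,
        acute_ie_pp=acute_ie,
        longterm_ic_pp=lt_ic,
        longterm_ie_pp=lt_ie,
        usual=uc,
        ai=ai,
        cohort_n=n,
    )


def _with_clinical(params: ModelParams, **kw) -> ModelParams:
    return replace(params, clinical=replace(params.clinical, **kw))


def _with_costs(params: ModelParams, **kw) -> ModelParams:
    return replace(params, costs=replace(params.costs, **kw))


def scenario_grid(
    params: ModelParams,
    mortality: MortalityTable,
    missed_values,
    reduction_values,
    ai_cost: float = 0.0,
) -> list[ScenarioCell]:
    """Incremental cost/QALYs over a (p_missed x reduction) grid, with the
    per-analysis AI fee overridden (0 by default, so each cell's cost saving
    is the headroom price at which the tool is still dominant).  Cells are
    ordered row-major by (p_missed, reduction)."""
    cells = []
    for m in missed_values:
        for r in reduction_values:
            p = _with_costs(
                _with_clinical(params, p_missed=float(m), reduction=float(r)),
                ai_per_analysis=float(ai_cost),
            )
            res = compare_strategies(p, mortality)
            cells.append(
                ScenarioCell(
                    p_missed=float(m),
                    reduction=float(r),
                    ai_cost=float(ai_cost),
                    ic_pp=res.ic_pp,
                    ie_pp=res.ie_pp,
                )
            )
    return cells


def price_performance_grid(
    params: ModelParams,
    mortality: MortalityTable,
    prices,
    reductions,
) -> pd.DataFrame:
    """Per-patient incremental cost at each (price per analysis, reduction).

    Because the fee is charged once per analyzed patient, the incremental
    cost is affine in the price with slope exactly 1; each column is
    evaluated once at price 0 and shifted.
    """
    prices = [float(p) for p in prices]
    if any(p < 0 for p in prices):
        raise ValueError("prices must be non-negative")
    ic0 = {}
    for r in reductions:
        p0 = _with_costs(
            _with_clinical(params, reduction=float(r)), ai_per_analysis=0.0
        )
        ic0[float(r)] = compare_strategies(p0, mortality).ic_pp
    data = {r: [ic + price for price in prices] for r, ic in ic0.items()}
    df = pd.DataFrame(data, index=pd.Index(prices, name="price"))
    df.columns.name = "reduction"
    return df


def threshold_price(params: ModelParams, mortality: MortalityTable) -> float:
    """Maximum price per AI analysis at which the AI strategy is still
    dominant (cost-neutral headroom price), to the nearest dollar."""
    p0 = _with_costs(params, ai_per_analysis=0.0)
    ic0 = compare_strategies(p0, mortality).ic_pp
    return float(round(max(0.0, -ic0)))


# ---------------------------------------------------------------------------
# One-way sensitivity

# name -> how to apply a value: scalar field on a section, or a scale factor
# applied to a whole per-state vector.
_SCALAR_PARAMS = {
    "p_lvo": "clinical",
    "p_eligible": "clinical",
    "p_missed": "clinical",
    "reduction": "clinical",
    "p_recurrent": "clinical",
    "age0": "clinical",
    "tx_iat": "costs",
    "tx_no_iat": "costs",
    "ai_per_analysis": "costs",
    "discount_costs": "costs",
    "discount_utilities": "utilities",
    "acute_year_fraction": "settings",
}
_SCALE_PARAMS = {
    "acute_costs_scale": ("costs", "acute_by_state"),
    "longterm_costs_scale": ("costs", "longterm_by_state"),
    "utilities_scale": ("utilities", "utility_by_state"),
}


def set_param(params: ModelParams, name: str, value: float) -> ModelParams:
    """Return params with one named parameter set (scalars) or a per-state
    vector multiplied by ``value`` (``*_scale`` names; utilities are capped
    at 1)."""
    if name in _SCALAR_PARAMS:
        section = _SCALAR_PARAMS[name]
        if name == "age0":
            value = int(round(value))
        return replace(params, **{section: replace(getattr(params, section), **{name: value})})
    if name in _SCALE_PARAMS:
        section, attr = _SCALE_PARAMS[name]
        vec = np.asarray(getattr(getattr(params, section), attr), dtype=float) * value
        if attr == "utility_by_state":
            vec = np.minimum(vec, 1.0)
        return replace(
            params, **{section: replace(getattr(params, section), **{attr: tuple(vec)})}
        )
    raise ValueError(f"unknown sensitivity parameter {name!r}")


def default_tornado_bounds(params: ModelParams) -> dict[str, tuple[float, float]]:
    """+/-20% bounds on the clinical probabilities, costs and discount rates
    not already varied in the scenario analysis, and +/-10 years on the
    starting age."""
    c, k = params.clinical, params.costs
    pm = lambda x: (0.8 * x, min(1.2 * x, 1.0))  # probability bounds capped at 1
    return {
        "p_lvo": pm(c.p_lvo),
        "p_eligible": pm(c.p_eligible),
        "p_recurrent": pm(c.p_recurrent),
        "tx_iat": (0.8 * k.tx_iat, 1.2 * k.tx_iat),
        "tx_no_iat": (0.8 * k.tx_no_iat, 1.2 * k.tx_no_iat),
        "acute_costs_scale": (0.8, 1.2),
        "longterm_costs_scale": (0.8, 1.2),
        "discount_costs": (0.8 * k.discount_costs, 1.2 * k.discount_costs),
        "discount_utilities": (
            0.8 * params.utilities.discount_utilities,
            1.2 * params.utilities.discount_utilities,
        ),
        "age0": (c.age0 - 10, c.age0 + 10),
    }


def one_way_sensitivity(
    params: ModelParams,
    mortality: MortalityTable,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoRow]:
    """Re-run the comparison at each parameter's low and high bound, one at a
    time, all else at base case; rows sorted by cost spread descending."""
    if bounds is None:
        bounds = default_tornado_bounds(params)
    rows = []
    for name, (low, high) in bounds.items():
        if low > high:
            raise ValueError(f"bounds for {name!r} must satisfy low <= high")
        res_lo = compare_strategies(set_param(params, name, low), mortality)
        res_hi = compare_strategies(set_param(params, name, high), mortality)
        rows.append(
            TornadoRow(
                parameter=name,
                low=float(low),
                high=float(high),
                ic_low=res_lo.ic_pp,
                ic_high=res_hi.ic_pp,
                ie_low=res_lo.ie_pp,
                ie_high=res_hi.ie_pp,
            )
        )
    rows.sort(key=lambda r: r.ic_spread, reverse=True)
    return rows


def population_scale(result: IncrementalResult, cohort_n: int) -> tuple[float, float]:
    """Scale per-patient increments to a yearly cohort: (cost total, QALY total)."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    return result.ic_pp * cohort_n, result.ie_pp * cohort_n


# ---------------------------------------------------------------------------
# Report frames (dollars to the nearest integer, QALYs to 4 decimals)


def base_case_frame(result: IncrementalResult) -> pd.DataFrame:
    """Phase-decomposed incremental results: population, per patient, and
    percent of the usual-care absolute totals."""
    n = result.cohort_n
    uc = result.usual
    rows = []
    for phase, ic, ie, uc_c, uc_q in (
        ("acute (<90 days)", result.acute_ic_pp, result.acute_ie_pp, uc.acute_cost_pp, uc.acute_qaly_pp),
        ("rest of life (>90 days)", result.longterm_ic_pp, result.longterm_ie_pp, uc.longterm_cost_pp, uc.longterm_qaly_pp),
        ("total", result.ic_pp, result.ie_pp, uc.cost_pp, uc.qaly_pp),
    ):
        rows.append(
            {
                "phase": phase,
                "ic_population": round(ic * n),
                "ic_patient": round(ic),
                "ic_pct_usual_care": round(100 * ic / uc.cost_pp, 2) if uc.cost_pp else float("nan"),
                "ie_population": round(ie * n, 2),
                "ie_patient": round(ie, 4),
                "ie_pct_usual_care": round(100 * ie / uc.qaly_pp, 2) if uc.qaly_pp else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def scenario_grid_frame(cells: list[ScenarioCell]) -> pd.DataFrame:
    """Long-format scenario grid (one row per cell, rounded for reporting)."""
    return pd.DataFrame(
        {
            "p_missed": [c.p_missed for c in cells],
            "reduction": [c.reduction for c in cells],
            "ai_cost": [c.ai_cost for c in cells],
            "ic_pp": [round(c.ic_pp) for c in cells],
            "ie_pp": [round(c.ie_pp, 4) for c in cells],
        }
    )


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low": [r.low for r in rows],
            "high": [r.high for r in rows],
            "ic_low": [round(r.ic_low) for r in rows],
            "ic_high": [round(r.ic_high) for r in rows],
            "ie_low": [round(r.ie_low, 4) for r in rows],
            "ie_high": [round(r.ie_high, 4) for r in rows],
        }
    )
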