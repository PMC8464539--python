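"""Lifetime Markov cohort model over mRS states.

The 90-day cohort distribution is propagated through yearly cycles.  Within
each cycle, hazards are applied sequentially: first background mortality at
the general-population annual death probability for the cohort's current age,
then recurrent stroke among survivors.  Recurrent-stroke outcomes follow the
untreated (no-IAT) 90-day distribution under a no-improvement constraint —
a recurrence can leave the mRS state unchanged or worsen it, never improve it.
Costs and utilities accrue at the end of each cycle on the post-transition
occupancy and are discounted geometrically (costs and utilities at their own
annual rates).

A seeded patient-level microsimulation of the identical rules serves as an
independent oracle for the deterministic cohort engine.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetables import MortalityTable
from .params import DEATH, N_STATES, ModelParams, MrsDistribution

__all__ = [
    "Trajectory",
    "LifetimeResult",
    "MicrosimResult",
    "recurrence_matrix",
    "transition",
    "run_markov",
    "microsim_oracle",
]


@dataclass(frozen=True)
class Trajectory:
    """Cohort occupancy per cycle.

    ``occupancy`` has one row per cycle 0..cycles (row 0 is the 90-day
    distribution), columns mRS 0-5 and death.  ``cycle_costs`` and
    ``cycle_qalys`` hold the discounted accrual of each cycle (row 0 is 0).
    """

    occupancy: np.ndarray
    ages: np.ndarray
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy, columns=[f"mrs{i}" for i in range(DEATH)] + ["death"]
        )
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "age", self.ages)
        df["disc_cost"] = self.cycle_costs
        df["disc_qaly"] = self.cycle_qalys
        return df


@dataclass(frozen=True)
class LifetimeResult:
    """Discounted long-term cost and QALYs per patient, with the trajectory."""

    cost_pp: float
    qaly_pp: float
    trajectory: Trajectory


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimate of the lifetime result with standard errors."""

    cost_pp: float
    qaly_pp: float
    cost_se: float
    qaly_se: float
    n_patients: int
    seed: int


def recurrence_matrix(params: ModelParams) -> np.ndarray:
    """Row s: distribution over post-recurrence states for a patient
    currently in alive state s, under the configured no-improvement rule.

    clamp_max: new state = max(s, draw from the no-IAT distribution) with a
    death draw always fatal.  truncate_renormalize: the no-IAT distribution
    restricted to states >= s (death included) and renormalized.
    """
    q = params.clinical.mrs_no_iat.as_array()
    rule = params.settings.recurrence_rule
    R = np.zeros((DEATH, N_STATES))
    for s in range(DEATH):
        if rule == "clamp_max":
            R[s, s] = q[: s + 1].sum()
            R[s, s + 1 :] = q[s + 1 :]
        elif rule == "truncate_renormalize":
            tail = q[s:].sum()
            if tail <= 0.0:  # degenerate custom distribution: stay put
                R[s, s] = 1.0
            else:
                R[s, s:] = q[s:] / tail
        else:
            raise ValueError(f"unknown recurrence_rule {rule!r}")
    return R


def _step(
    alive: np.ndarray,
    dead: float,
    age: int,
    params: ModelParams,
    mortality: MortalityTable,
    R: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """One cycle on an (unnormalized) alive-mass vector.

    Returns (new alive mass, new dead mass, expected acute cost incurred by
    recurrent strokes this cycle — used only when recurrence_acute_costs).
    """
    qx = mortality.qx_at(age)
    survivors = alive * (1.0 - qx)
    dead += float(alive.sum()) * qx

    p_rec = params.clinical.p_recurrent
    recurrent = survivors * p_rec
    redistributed = recurrent @ R  # (7,)
    new_alive = survivors - recurrent + redistributed[:DEATH]
    dead += float(redistributed[DEATH])

    rec_acute_cost = 0.0
    if params.settings.recurrence_acute_costs:
        acute = np.asarray(params.costs.acute_by_state, dtype=float)
        rec_acute_cost = float(recurrent @ (R @ acute))
    return new_alive, dead, rec_acute_cost


def transition(
    dist: MrsDistribution,
    age: int,
    params: ModelParams,
    mortality: MortalityTable,
) -> MrsDistribution:
    """Advance a cohort distribution by one yearly cycle (mortality, then
    recurrence) at the given attained age."""
    d = dist.as_array()
    R = recurrence_matrix(params)
    alive, dead, _ = _step(d[:DEATH], float(d[DEATH]), age, params, mortality, R)
    return MrsDistribution(np.append(alive, dead))


def run_markov(
    dist90: MrsDistribution,
    params: ModelParams,
    mortality: MortalityTable,
    healthy_fraction: float = 0.0,
) -> LifetimeResult:
    """Propagate the 90-day distribution over the configured yearly cycles.

    ``healthy_fraction`` is the share of the cohort (part of the mRS 0 mass
    of ``dist90``) that never had a stroke: it is subject to background
    mortality only — no recurrence, no long-term stroke costs — and accrues
    the mRS 0 utility while alive.  Cycle t uses the death probability at
    age ``age0 + t - 1``; accrual is end-of-cycle with discount exponent t.
    """
    d = dist90.as_array()
    if not 0.0 <= healthy_fraction <= d[0] + 1e-12:
        raise ValueError(
            f"healthy_fraction {healthy_fraction} exceeds the mRS 0 mass {d[0]}"
        )
    c, k, u, s = params.clinical, params.costs, params.utilities, params.settings
    lt_cost = np.asarray(k.longterm_by_state, dtype=float)
    util = np.asarray(u.utility_by_state, dtype=float)
    R = recurrence_matrix(params)

    stroke_alive = d[:DEATH].copy()
    stroke_alive[0] -= healthy_fraction
    healthy_alive = healthy_fraction
    dead = float(d[DEATH])

    n_rows = s.cycles + 1
    occupancy = np.zeros((n_rows, N_STATES))
    occupancy[0, :DEATH] = stroke_alive
    occupancy[0, 0] += healthy_alive
    occupancy[0, DEATH] = dead
    ages = c.age0 + np.arange(n_rows) - 1
    ages[0] = c.age0  # row 0 is the state at model entry
    cycle_costs = np.zeros(n_rows)
    cycle_qalys = np.zeros(n_rows)

    cost = 0.0
    qaly = 0.0
    for t in range(1, s.cycles + 1):
        age = c.age0 + t - 1
        stroke_alive, dead, rec_cost = _step(stroke_alive, dead, age, params, mortality, R)
        qx = mortality.qx_at(age)
        dead += healthy_alive * qx
        healthy_alive *= 1.0 - qx

        disc_c = (1.0 + k.discount_costs) ** t
        disc_u = (1.0 + u.discount_utilities) ** t
        ct = (float(stroke_alive @ lt_cost) + rec_cost) / disc_c
        qt = (float(stroke_alive @ util) + healthy_alive * util[0]) / disc_u
        cost += ct
        qaly += qt

        occupancy[t, :DEATH] = stroke_alive
        occupancy[t, 0] += healthy_alive
        occupancy[t, DEATH] = dead
        cycle_costs[t] = ct
        cycle_qalys[t] = qt

    traj = Trajectory(occupancy=occupancy, ages=ages, cycle_costs=cycle_costs, cycle_qalys=cycle_qalys)
    return LifetimeResult(cost_pp=cost, qaly_pp=qaly, trajectory=traj)


def microsim_oracle(
    dist90: MrsDistribution,
    params: ModelParams,
    mortality: MortalityTable,
    n_patients: int,
    seed: int,
    healthy_fraction: float = 0.0,
) -> MicrosimResult:
    """Patient-level Monte-Carlo simulation of the identical transition rules.

    Draws each patient's initial state from ``dist90`` (a ``healthy_fraction``
    share starts stroke-free at mRS 0) and simulates yearly death and
    recurrence draws, accruing discounted costs and QALYs per patient.
    Identical seeds give identical estimates.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    d = dist90.as_array()
    if not 0.0 <= healthy_fraction <= d[0] + 1e-12:
        raise ValueError("healthy_fraction exceeds the mRS 0 mass")
    rng = np.random.default_rng(seed)
    c, k, u, s = params.clinical, params.costs, params.utilities, params.settings

    # categorical over: healthy, stroke mRS0..5, dead
    probs = np.concatenate([[healthy_fraction], d])
    probs[1] = max(probs[1] - healthy_fraction, 0.0)
    probs = probs / probs.sum()
    draw = rng.choice(probs.size, size=n_patients, p=probs)
    healthy = draw == 0
    states = np.where(healthy, 0, draw - 1).astype(np.int64)

    lt_cost = np.asarray(k.longterm_by_state, dtype=float)
    util = np.asarray(u.utility_by_state, dtype=float)
    acute = np.asarray(k.acute_by_state, dtype=float)
    R = recurrence_matrix(params)
    R_cum = np.cumsum(R, axis=1)

    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    for t in range(1, s.cycles + 1):
        age = c.age0 + t - 1
        qx = mortality.qx_at(age)
        alive = states < DEATH
        dies = alive & (rng.random(n_patients) < qx)
        states[dies] = DEATH

        stroke_alive = (states < DEATH) & ~healthy
        recurs = stroke_alive & (rng.random(n_patients) < c.p_recurrent)
        idx = np.flatnonzero(recurs)
        if idx.size:
            uu = rng.random(idx.size)
            old = states[idx]
            new = np.empty(idx.size, dtype=np.int64)
            for st in range(DEATH):  # inverse-CDF draw per current state
                m = old == st
                if m.any():
                    new[m] = np.searchsorted(R_cum[st], uu[m], side="right")
            if s.recurrence_acute_costs:
                cost[idx] += acute[new] / (1.0 + k.discount_costs) ** t
            states[idx] = new

        disc_c = (1.0 + k.discount_costs) ** t
        disc_u = (1.0 + u.discount_utilities) ** t
        stroke_alive = (states < DEATH) & ~healthy
        healthy_alive = healthy & (states < DEATH)
        cost[stroke_alive] += lt_cost[states[stroke_alive]] / disc_c
        qaly[stroke_alive] += util[states[stroke_alive]] / disc_u
        qaly[healthy_alive] += util[0] / disc_u

    return MicrosimResult(
        cost_pp=float(cost.mean()),
        qaly_pp=float(qaly.mean()),
        cost_se=float(cost.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        qaly_se=float(qaly.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        n_patients=n_patients,
        seed=seed,
    )
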