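"""The Markov cohort engine: state space, transition matrices, cohort trace,
and discounted cost/QALY accrual.

The clinical model has four health states; recurrence is expanded into
tunnel sub-states so that first-year, second-year, and later recurrence
costs can differ:

    MS      menopausal symptoms (initial state)
    RED     clinically significant reduction in menopausal symptoms
    REC1-4  recurrence, 6-month tunnels covering years 1 and 2
    RECPOST recurrence beyond year 2
    DEAD    absorbing

The cohort starts fully in MS.  The strategy-specific response probability
(MS -> RED) applies in the first cycle only, mirroring a one-off treatment
effect estimated at the end of the trial; all other transitions recur every
cycle.  Within a cycle, recurrence and death are competing risks applied
before the response (the response reaches the surviving, non-recurring
mass), unless ``response_before_competing_risks`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .parameters import (
    ParameterSet,
    STRATEGIES,
    mortality_schedule,
    per_cycle_probability,
)

STATES = ("MS", "RED", "REC1", "REC2", "REC3", "REC4", "RECPOST", "DEAD")
MS, RED, REC1, REC2, REC3, REC4, RECPOST, DEAD = range(8)
N_STATES = len(STATES)
PERSPECTIVES = ("healthcare", "intervention")

__all__ = [
    "STATES",
    "N_STATES",
    "PERSPECTIVES",
    "CohortTrace",
    "StrategyResult",
    "discount_factor",
    "transition_matrix",
    "run_cohort",
    "accrue",
    "run_strategy",
]


@dataclass
class CohortTrace:
    """State-occupancy fractions of the cohort, one row per cycle boundary."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(0, "strategy", self.strategy)
        return df


@dataclass
class StrategyResult:
    """Discounted totals per patient for one strategy."""

    strategy: str
    perspective: str
    total_cost: float   # EUR, discounted
    total_qaly: float   # QALYs, discounted


def discount_factor(annual_rate: float, time: float) -> float:
    """``(1 + r)**(-t)`` with ``t`` in years."""
    if annual_rate < 0 or time < 0:
        raise ValueError("annual_rate and time must be non-negative")
    return (1.0 + annual_rate) ** (-time)


def _per_cycle_transition_probs(params: ParameterSet) -> Dict[str, float]:
    t = params.transitions
    if t.probs_are_annual:
        return {
            "p_rec": per_cycle_probability(t.p_to_recurrence, params.cycle_length),
            "p_rd": per_cycle_probability(t.p_rec_death, params.cycle_length),
        }
    return {"p_rec": t.p_to_recurrence, "p_rd": t.p_rec_death}


def transition_matrix(params: ParameterSet, strategy: str, cycle: int) -> np.ndarray:
    """One-cycle stochastic matrix for ``strategy`` at ``cycle`` (1-based)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 1 <= cycle <= params.n_cycles:
        raise ValueError(f"cycle {cycle} outside [1, {params.n_cycles}]")
    pc = _per_cycle_transition_probs(params)
    p_rec, p_rd = pc["p_rec"], pc["p_rd"]
    m = mortality_schedule(params.transitions, params.n_cycles,
                           params.cycle_length)[cycle - 1]
    r = params.transitions.p_response[strategy] if cycle == 1 else 0.0

    T = np.zeros((N_STATES, N_STATES))
    if params.response_before_competing_risks:
        to_red = r
        if to_red + p_rec + m > 1.0 + 1e-12:
            raise ValueError(
                "inconsistent parameters: response + recurrence + mortality > 1"
            )
    else:
        to_red = r * (1.0 - p_rec - m)
        if p_rec + m > 1.0 + 1e-12:
            raise ValueError("inconsistent parameters: recurrence + mortality > 1")
    T[MS, RED] = to_red
    T[MS, REC1] = p_rec
    T[MS, DEAD] = m
    T[MS, MS] = 1.0 - to_red - p_rec - m
    T[RED, REC1] = p_rec
    T[RED, DEAD] = m
    T[RED, RED] = 1.0 - p_rec - m
    for k, nxt in ((REC1, REC2), (REC2, REC3), (REC3, REC4), (REC4, RECPOST)):
        T[k, DEAD] = p_rd
        T[k, nxt] = 1.0 - p_rd
    T[RECPOST, DEAD] = p_rd
    T[RECPOST, RECPOST] = 1.0 - p_rd
    T[DEAD, DEAD] = 1.0
    if (T < -1e-12).any():
        raise ValueError("inconsistent parameters yield negative probabilities")
    return T


def run_cohort(params: ParameterSet, strategy: str) -> CohortTrace:
    """Propagate the cohort through all cycles.

    If the treatment effect expires before the horizon
    (``effect_duration_cycles`` < ``n_cycles``), the reduced-symptoms
    occupancy reverts to the symptomatic state in one step at the start of
    the first cycle past the effect duration.
    """
    n = params.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0, MS] = 1.0
    expiry = params.effect_duration_cycles
    for c in range(1, n + 1):
        prev = occ[c - 1].copy()
        if expiry is not None and c == expiry + 1:
            prev[MS] += prev[RED]
            prev[RED] = 0.0
        occ[c] = prev @ transition_matrix(params, strategy, c)
    return CohortTrace(strategy=strategy, occupancy=occ)


def _state_cost_vector(params: ParameterSet, perspective: str) -> np.ndarray:
    if perspective == "intervention":
        return np.zeros(N_STATES)
    c = params.costs
    half_year1 = c.rec_year1_cost * params.cycle_length
    half_year2 = c.rec_year2_cost * params.cycle_length
    return np.array([
        c.state_cost_ms, c.state_cost_red,
        half_year1, half_year1, half_year2, half_year2,
        c.rec_post_cost, 0.0,
    ])


def accrue(trace: CohortTrace, params: ParameterSet, strategy: str,
           perspective: str = "healthcare") -> StrategyResult:
    """Discounted per-patient totals from a cohort trace.

    Per cycle, cost = occupancy x per-cycle state cost and QALY = occupancy
    x utility x cycle length, each discounted at its annual rate.  The
    occupancy row used and the discount time follow ``params.accrual``:
    cycle start (default), cycle end, or the mid-cycle average (half-cycle
    correction).  The one-off intervention cost enters undiscounted at time
    zero; under the intervention perspective it is the only cost.
    """
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    cl = params.cycle_length
    u = np.array([params.utilities.u_ms, params.utilities.u_red]
                 + [params.utilities.u_rec] * 5 + [params.utilities.u_dead])
    cost_v = _state_cost_vector(params, perspective)
    occ = trace.occupancy
    total_cost = params.costs.intervention_cost[strategy]
    total_qaly = 0.0
    for c in range(1, trace.n_cycles + 1):
        if params.accrual == "begin":
            row, t = occ[c - 1], (c - 1) * cl
        elif params.accrual == "end":
            row, t = occ[c], c * cl
        else:  # half_cycle
            row, t = 0.5 * (occ[c - 1] + occ[c]), (c - 0.5) * cl
        total_qaly += float(row @ u) * cl * discount_factor(params.discount_effects, t)
        total_cost += float(row @ cost_v) * discount_factor(params.discount_costs, t)
    return StrategyResult(strategy=strategy, perspective=perspective,
                          total_cost=total_cost, total_qaly=total_qaly)


def run_strategy(params: ParameterSet, strategy: str,
                 perspective: str = "healthcare") -> StrategyResult:
    """Convenience: trace the cohort and accrue in one call."""
    return accrue(run_cohort(params, strategy), params, strategy, perspective)
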