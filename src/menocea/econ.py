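"""Economic evaluation on top of strategy results: incremental cost-utility
ratios, number-needed-to-treat cost-effectiveness, and budget impact."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import pandas as pd

from .markov import StrategyResult, run_strategy
from .parameters import BiaConfig, ParameterSet

__all__ = [
    "IncrementalResult",
    "NntResult",
    "BiaResult",
    "incremental",
    "nnt_from_probabilities",
    "cost_per_responder",
    "budget_impact",
    "mix_budget_impact",
    "deterministic_table",
]


@dataclass
class IncrementalResult:
    comparator: str
    delta_cost: float   # EUR
    delta_qaly: float   # QALY
    icur: Optional[float]  # EUR/QALY; None when flagged
    flag: Optional[str] = None  # "dominant", "dominated", or "undefined"


@dataclass
class NntResult:
    arr: float               # absolute risk reduction
    nnt: Optional[float]     # 1/ARR when ARR > 0
    no_benefit: bool = False


@dataclass
class BiaResult:
    strategy_or_mix: str
    annual_budget_impact: float  # EUR per year
    perspective: str


def incremental(intervention: StrategyResult, control: StrategyResult) -> IncrementalResult:
    """Incremental cost-utility of ``intervention`` against ``control``.

    The ICUR is incremental cost over incremental QALYs.  When the
    intervention is cheaper and more effective it dominates (no ratio is
    reported); when costlier and less effective it is dominated; a zero QALY
    difference leaves the ratio undefined.
    """
    if intervention.perspective != control.perspective:
        raise ValueError(
            f"perspective mismatch: {intervention.perspective} vs {control.perspective}"
        )
    dc = intervention.total_cost - control.total_cost
    dq = intervention.total_qaly - control.total_qaly
    if dq == 0.0:
        return IncrementalResult(control.strategy, dc, dq, None, "undefined")
    if dc < 0 and dq > 0:
        return IncrementalResult(control.strategy, dc, dq, None, "dominant")
    if dc > 0 and dq < 0:
        return IncrementalResult(control.strategy, dc, dq, None, "dominated")
    return IncrementalResult(control.strategy, dc, dq, dc / dq, None)


def nnt_from_probabilities(p_intervention: float, p_control: float) -> NntResult:
    """Number needed to treat from two response probabilities (NNT = 1/ARR)."""
    for p in (p_intervention, p_control):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    arr = p_intervention - p_control
    if arr <= 0:
        return NntResult(arr=arr, nnt=None, no_benefit=True)
    return NntResult(arr=arr, nnt=1.0 / arr)


def cost_per_responder(nnt: float, delta_cost: float) -> float:
    """Incremental cost to obtain one clinically significant response.

    ``nnt`` may come from :func:`nnt_from_probabilities` or be supplied
    directly (e.g. an NNT computed on unrounded trial proportions).
    """
    if nnt <= 0:
        raise ValueError("nnt must be positive")
    return nnt * delta_cost


def budget_impact(delta_cost_per_patient: float, config: BiaConfig,
                  label: str = "", perspective: str = "healthcare") -> BiaResult:
    """Annual budget impact: per-patient incremental cost x treated population."""
    if config.annual_population < 0:
        raise ValueError("annual_population must be >= 0")
    return BiaResult(
        strategy_or_mix=label,
        annual_budget_impact=delta_cost_per_patient * config.annual_population,
        perspective=perspective,
    )


def mix_budget_impact(delta_costs: Dict[str, float], config: BiaConfig,
                      perspective: str = "healthcare") -> BiaResult:
    """Budget impact of an uptake mix across strategies (weights sum to 1)."""
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    missing = set(config.mix_weights) - set(delta_costs)
    if missing:
        raise ValueError(f"missing incremental costs for strategies: {sorted(missing)}")
    weighted = sum(config.mix_weights[s] * delta_costs[s] for s in config.mix_weights)
    label = "+".join(f"{s}:{w:g}" for s, w in sorted(config.mix_weights.items()))
    return budget_impact(weighted, config, label=label, perspective=perspective)


def deterministic_table(params: ParameterSet, perspective: str = "healthcare",
                        control: str = "waitlist") -> pd.DataFrame:
    """Full deterministic evaluation: one row per strategy with costs, QALYs,
    increments versus the control, ICUR, and annual budget impact."""
    results = {s: run_strategy(params, s, perspective)
               for s in params.transitions.p_response}
    rows = []
    for s, res in results.items():
        if s == control:
            rows.append({"strategy": s, "perspective": perspective,
                         "cost_eur": res.total_cost, "qaly": res.total_qaly,
                         "delta_cost_eur": None, "delta_qaly": None,
                         "icur_eur_per_qaly": None, "bia_eur_per_year": None})
            continue
        inc = incremental(res, results[control])
        bia = budget_impact(inc.delta_cost, params.bia, label=s,
                            perspective=perspective)
        rows.append({"strategy": s, "perspective": perspective,
                     "cost_eur": res.total_cost, "qaly": res.total_qaly,
                     "delta_cost_eur": inc.delta_cost, "delta_qaly": inc.delta_qaly,
                     "icur_eur_per_qaly": inc.icur if inc.icur is not None else inc.flag,
                     "bia_eur_per_year": bia.annual_budget_impact})
    return pd.DataFrame(rows)
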