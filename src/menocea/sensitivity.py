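"""Deterministic sensitivity and scenario analyses.

One-way analyses re-run the cohort model with a single parameter pushed to
a low and a high value and record the ICUR against the waitlist control at
each; the tornado ranks parameters by the resulting ICUR swing.  Default
ranges are mean ± 1.96 SE where a standard error is configured and
mean ± 20% otherwise.  Named scenarios cover the shortened treatment-effect
duration (3 instead of 5 years) and the intervention-cost-only perspective.
All transformations are pure: the input parameter set is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .econ import IncrementalResult, BiaResult, budget_impact, deterministic_table, incremental, mix_budget_impact
from .markov import StrategyResult, run_strategy
from .parameters import ParameterSet

__all__ = [
    "TornadoRow",
    "ScenarioSpec",
    "SCENARIOS",
    "get_parameter",
    "set_parameter",
    "one_way",
    "default_ranges",
    "tornado",
    "run_scenario",
]


@dataclass
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    icur_at_low: Optional[float]
    icur_at_high: Optional[float]
    swing: float  # |icur_high - icur_low|, EUR/QALY


@dataclass
class ScenarioSpec:
    name: str
    overrides: Dict[str, object] = field(default_factory=dict)
    perspective: str = "healthcare"


# addressable parameter paths -> (getter, setter); setters mutate in place
# and are applied to a fresh copy by set_parameter.
def _path_error(path: str) -> ValueError:
    return ValueError(f"unknown parameter path {path!r}")


def get_parameter(params: ParameterSet, path: str) -> float:
    parts = path.split(".")
    if parts[0] == "utilities" and len(parts) == 2 and hasattr(params.utilities, parts[1]):
        return getattr(params.utilities, parts[1])
    if parts[0] == "transitions":
        if parts[1] == "p_response" and len(parts) == 3:
            return params.transitions.p_response[parts[2]]
        if len(parts) == 2 and parts[1] in ("p_to_recurrence", "p_rec_death"):
            return getattr(params.transitions, parts[1])
    if parts[0] == "costs":
        if parts[1] == "intervention_cost" and len(parts) == 3:
            return params.costs.intervention_cost[parts[2]]
        if len(parts) == 2 and parts[1] in ("state_cost_ms", "state_cost_red",
                                            "rec_year1_cost", "rec_year2_cost"):
            return getattr(params.costs, parts[1])
    if path == "effect_duration_cycles":
        ed = params.effect_duration_cycles
        return float(params.n_cycles if ed is None else ed)
    raise _path_error(path)


def set_parameter(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with the addressed parameter set to ``value``.

    Aggregate state and recurrence costs are set by rescaling their item
    breakdown proportionally, so the probabilistic specs stay consistent.
    """
    out = params.copy()
    parts = path.split(".")
    if parts[0] == "utilities" and len(parts) == 2 and hasattr(out.utilities, parts[1]):
        setattr(out.utilities, parts[1], float(value))
        return out
    if parts[0] == "transitions":
        if parts[1] == "p_response" and len(parts) == 3:
            out.transitions.p_response[parts[2]] = float(value)
            return out
        if len(parts) == 2 and parts[1] in ("p_to_recurrence", "p_rec_death"):
            setattr(out.transitions, parts[1], float(value))
            return out
    if parts[0] == "costs":
        if parts[1] == "intervention_cost" and len(parts) == 3:
            out.costs.intervention_cost[parts[2]] = float(value)
            return out
        if parts[1] == "state_cost_ms":
            out.costs.scale_state_cost("menopausal_symptoms", float(value))
            return out
        if parts[1] == "state_cost_red":
            out.costs.scale_state_cost("reduction", float(value))
            return out
        if parts[1] in ("rec_year1_cost", "rec_year2_cost"):
            year = "year1" if parts[1].startswith("rec_year1") else "year2"
            current = sum(out.costs.recurrence_costs[year].values())
            f = float(value) / current
            out.costs.recurrence_costs[year] = {
                k: v * f for k, v in out.costs.recurrence_costs[year].items()
            }
            return out
    if path == "effect_duration_cycles":
        out.effect_duration_cycles = int(value)
        return out
    raise _path_error(path)


def _icur_vs_control(params: ParameterSet, strategy: str,
                     control: str = "waitlist",
                     perspective: str = "healthcare") -> Optional[float]:
    inc = incremental(run_strategy(params, strategy, perspective),
                      run_strategy(params, control, perspective))
    return inc.icur


def one_way(params: ParameterSet, parameter: str, low: float, high: float,
            strategy: str, control: str = "waitlist",
            perspective: str = "healthcare") -> TornadoRow:
    """Re-run the model with one parameter at its low and high value."""
    if low > high:
        raise ValueError("low must be <= high")
    icur_low = _icur_vs_control(set_parameter(params, parameter, low),
                                strategy, control, perspective)
    icur_high = _icur_vs_control(set_parameter(params, parameter, high),
                                 strategy, control, perspective)
    if icur_low is None or icur_high is None:
        # an extreme flips the comparison into dominance: rank it first
        swing = float("inf") if low < high else 0.0
    else:
        swing = abs(icur_high - icur_low)
    return TornadoRow(parameter=parameter, low_value=low, high_value=high,
                      icur_at_low=icur_low, icur_at_high=icur_high, swing=swing)


def default_ranges(params: ParameterSet, strategy: str) -> Dict[str, Tuple[float, float]]:
    """Low/high values per parameter: mean ± 1.96 SE where an SE is
    configured, mean ± 20% otherwise; effect duration spans 3 to 5 years."""
    ranges: Dict[str, Tuple[float, float]] = {}

    def around(path: str, se: Optional[float], clip01: bool = False) -> None:
        mean = get_parameter(params, path)
        half = 1.96 * se if se else 0.2 * mean
        lo, hi = mean - half, mean + half
        if clip01:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[path] = (lo, hi)

    specs = params.psa_specs
    for u in ("u_ms", "u_red", "u_rec"):
        spec = specs.get(f"utilities.{u}")
        around(f"utilities.{u}", spec.se if spec else None, clip01=True)
    around(f"transitions.p_response.{strategy}", None, clip01=True)
    around("transitions.p_to_recurrence", None, clip01=True)
    around("transitions.p_rec_death", None, clip01=True)
    f = params.cost_se_fraction  # cost SEs follow the ±20%-of-mean rule
    for c in ("state_cost_ms", "state_cost_red", "rec_year1_cost", "rec_year2_cost"):
        around(f"costs.{c}", f * get_parameter(params, f"costs.{c}") or None)
    around(f"costs.intervention_cost.{strategy}",
           f * get_parameter(params, f"costs.intervention_cost.{strategy}") or None)
    half_years = 2  # 3- to 5-year effect duration around the base horizon
    ranges["effect_duration_cycles"] = (
        float(params.n_cycles - 2 * half_years), float(params.n_cycles))
    return ranges


def tornado(params: ParameterSet, strategy: str,
            ranges: Optional[Dict[str, Tuple[float, float]]] = None,
            control: str = "waitlist",
            perspective: str = "healthcare") -> List[TornadoRow]:
    """One-way analyses for every configured parameter, sorted by swing."""
    if ranges is None:
        ranges = default_ranges(params, strategy)
    rows = [one_way(params, p, lo, hi, strategy, control, perspective)
            for p, (lo, hi) in ranges.items()]
    rows.sort(key=lambda r: -r.swing)
    return rows


def tornado_frame(rows: List[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


SCENARIOS: Dict[str, ScenarioSpec] = {
    "base_case": ScenarioSpec("base_case"),
    "effect_duration_3y": ScenarioSpec(
        "effect_duration_3y", overrides={"effect_duration_cycles": 6}),
    "intervention_perspective": ScenarioSpec(
        "intervention_perspective", perspective="intervention"),
}


def run_scenario(params: ParameterSet, spec) -> Dict[str, object]:
    """Evaluate a named or explicit scenario end to end.

    Returns a bundle with per-strategy results, incremental results versus
    the waitlist, per-strategy budget impacts, and the mixed-uptake budget
    impact.  In the 3-year-effect scenario responders revert to the
    symptomatic state at the start of cycle 7; under the intervention
    perspective only intervention costs count.
    """
    if isinstance(spec, str):
        if spec not in SCENARIOS:
            raise ValueError(f"unknown scenario {spec!r}")
        spec = SCENARIOS[spec]
    p = params.copy()
    for path, value in spec.overrides.items():
        p = set_parameter(p, path, value)
    strategies = list(p.transitions.p_response)
    results = {s: run_strategy(p, s, spec.perspective) for s in strategies}
    incs = {s: incremental(results[s], results["waitlist"])
            for s in strategies if s != "waitlist"}
    bias = {s: budget_impact(inc.delta_cost, p.bia, label=s,
                             perspective=spec.perspective)
            for s, inc in incs.items()}
    mix = mix_budget_impact({s: inc.delta_cost for s, inc in incs.items()},
                            p.bia, perspective=spec.perspective)
    return {"scenario": spec.name, "perspective": spec.perspective,
            "results": results, "incrementals": incs, "bia": bias,
            "bia_mix": mix,
            "table": deterministic_table(p, spec.perspective)}
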