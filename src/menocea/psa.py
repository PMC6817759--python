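"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: utilities are drawn
from method-of-moments beta distributions, every cost item from a gamma
distribution with standard error a fixed fraction of its mean (the "±20%"
rule), and each arm's first-cycle response probability from a two-component
Dirichlet (equivalently a beta) scaled by an effective sample size — arms
are independent samples, so no joint vector is drawn.  The recurrence and
recurrence-mortality probabilities ship without a dispersion estimate and
stay fixed unless their spec is overridden.  Each draw re-runs the cohort
model for all strategies; summaries are cost-effectiveness acceptability
curves (CEACs) and cost-effectiveness-plane quadrant fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .markov import run_strategy
from .parameters import ParameterSet, ValidationError

__all__ = [
    "PsaConfig",
    "PsaResult",
    "CeacCurve",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "dirichlet_counts",
    "draw_parameter_set",
    "run_psa",
    "ceac",
    "ne_quadrant_fraction",
    "quadrant_fractions",
    "default_wtp_grid",
]

_CONC_FLOOR = 1e-9  # concentration floor for degenerate Dirichlet components


def beta_from_mean_se(mean: float, se: float) -> Tuple[float, float]:
    """Method-of-moments (alpha, beta) shape parameters from mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if not 0.0 < se ** 2 < mean * (1.0 - mean):
        raise ValueError(f"infeasible beta se {se} for mean {mean}")
    nu = mean * (1.0 - mean) / se ** 2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> Tuple[float, float]:
    """Method-of-moments (shape, scale) from mean and SE.

    With the ±20% rule (se = 0.2 x mean) the shape is always 25.
    """
    if mean <= 0 or se <= 0:
        raise ValueError("gamma requires mean > 0 and se > 0")
    shape = (mean / se) ** 2
    return shape, se ** 2 / mean


def dirichlet_counts(probs: Sequence[float], ess: float) -> np.ndarray:
    """Dirichlet concentration vector: probabilities x effective sample size."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities sum to {probs.sum()}, not 1")
    if ess <= 0:
        raise ValueError("ess must be positive")
    return np.maximum(probs * ess, _CONC_FLOOR)


@dataclass
class PsaConfig:
    n_draws: int = 5000
    seed: int = 0
    wtp_grid: List[float] = field(default_factory=lambda: default_wtp_grid())
    comparison_mode: str = "pairwise_vs_control"  # or "multiway"
    perspective: str = "healthcare"
    control: str = "waitlist"

    def validate(self) -> "PsaConfig":
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if not self.wtp_grid:
            raise ValidationError("wtp_grid must not be empty")
        if any(w < 0 for w in self.wtp_grid):
            raise ValidationError("wtp_grid values must be >= 0")
        if self.comparison_mode not in {"pairwise_vs_control", "multiway"}:
            raise ValidationError(f"unknown comparison_mode {self.comparison_mode!r}")
        return self


def default_wtp_grid(top: float = 80_000.0, step: float = 2_500.0) -> List[float]:
    """EUR/QALY grid from 0 to ``top``; always contains the 30,000 threshold."""
    grid = list(np.arange(0.0, top + step / 2, step))
    if 30_000.0 not in grid:
        grid.append(30_000.0)
        grid.sort()
    return grid


@dataclass
class PsaResult:
    strategies: List[str]
    costs: np.ndarray   # (n_draws, n_strategies), EUR
    qalys: np.ndarray   # (n_draws, n_strategies)
    seed: int
    perspective: str

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(pd.DataFrame({
                "draw": np.arange(self.n_draws), "strategy": s,
                "cost_eur": self.costs[:, j], "qaly": self.qalys[:, j],
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class CeacCurve:
    strategies: List[str]
    wtp: np.ndarray            # (n_wtp,)
    probability: np.ndarray    # (n_wtp, n_strategies)
    mode: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=self.strategies)
        df.insert(0, "wtp_eur_per_qaly", self.wtp)
        return df


def draw_parameter_set(params: ParameterSet, rng: np.random.Generator,
                       max_retries: int = 100) -> ParameterSet:
    """Sample one parameter set from the configured uncertainty distributions.

    Parameters whose spec is ``fixed`` (and any quantity without a spec or a
    cost mean of zero) pass through unchanged.  A drawn set that fails
    validation is resampled up to ``max_retries`` times.
    """
    for _ in range(max_retries):
        draw = params.copy()
        specs = params.psa_specs
        # utilities ~ beta
        for name in ("u_ms", "u_red", "u_rec"):
            spec = specs.get(f"utilities.{name}")
            if spec is None or spec.kind == "fixed":
                continue
            a, b = beta_from_mean_se(getattr(params.utilities, name), spec.se)
            setattr(draw.utilities, name, float(rng.beta(a, b)))
        # response probabilities ~ per-arm two-component Dirichlet
        resp_spec = specs.get("transitions.p_response")
        if resp_spec is not None and resp_spec.kind == "dirichlet":
            for strat, p in params.transitions.p_response.items():
                conc = dirichlet_counts([p, 1.0 - p], resp_spec.ess)
                draw.transitions.p_response[strat] = float(rng.dirichlet(conc)[0])
        # optional beta uncertainty on recurrence/death probabilities
        for name in ("p_to_recurrence", "p_rec_death"):
            spec = specs.get(f"transitions.{name}")
            if spec is None or spec.kind == "fixed" or spec.se is None:
                continue
            a, b = beta_from_mean_se(getattr(params.transitions, name), spec.se)
            setattr(draw.transitions, name, float(rng.beta(a, b)))
        # every cost item ~ gamma with se = cost_se_fraction x mean
        f = params.cost_se_fraction
        if f > 0:
            def g(mean: float) -> float:
                if mean <= 0:
                    return mean
                shape, scale = gamma_from_mean_se(mean, f * mean)
                return float(rng.gamma(shape, scale))

            c = draw.costs
            c.intervention_cost = {k: g(v) for k, v in c.intervention_cost.items()}
            c.provider_costs = {
                state: {cat: g(v) for cat, v in cats.items()}
                for state, cats in c.provider_costs.items()
            }
            c.recurrence_costs = {
                year: {cat: g(v) for cat, v in items.items()}
                for year, items in c.recurrence_costs.items()
            }
        try:
            return draw.validate()
        except ValidationError:
            continue
    raise ValidationError(f"no valid parameter draw within {max_retries} attempts")


def run_psa(params: ParameterSet, config: PsaConfig) -> PsaResult:
    """Monte Carlo evaluation: one cohort-model run per draw and strategy."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    strategies = list(params.transitions.p_response)
    costs = np.empty((config.n_draws, len(strategies)))
    qalys = np.empty_like(costs)
    for i in range(config.n_draws):
        draw = draw_parameter_set(params, rng)
        for j, s in enumerate(strategies):
            res = run_strategy(draw, s, config.perspective)
            costs[i, j] = res.total_cost
            qalys[i, j] = res.total_qaly
    if not (np.isfinite(costs).all() and np.isfinite(qalys).all()):
        raise ValidationError("non-finite PSA draws")
    return PsaResult(strategies=strategies, costs=costs, qalys=qalys,
                     seed=config.seed, perspective=config.perspective)


def ceac(psa: PsaResult, config: PsaConfig) -> CeacCurve:
    """Cost-effectiveness acceptability curves over the WTP grid.

    Pairwise mode: for each intervention, the fraction of draws whose net
    monetary benefit (NMB = WTP x QALY - cost) beats the control's, ties
    split equally.  Multiway mode: the fraction of draws where each strategy
    attains the maximal NMB; probabilities sum to 1 at every WTP.
    """
    config.validate()
    wtp = np.asarray(sorted(config.wtp_grid), dtype=float)
    n_s = len(psa.strategies)
    prob = np.zeros((len(wtp), n_s))
    ctrl = psa.strategies.index(config.control)
    for i, w in enumerate(wtp):
        nmb = w * psa.qalys - psa.costs  # (draws, strategies)
        if config.comparison_mode == "pairwise_vs_control":
            for j in range(n_s):
                if j == ctrl:
                    prob[i, j] = np.nan
                    continue
                diff = nmb[:, j] - nmb[:, ctrl]
                prob[i, j] = np.mean((diff > 0) + 0.5 * (diff == 0))
        else:
            best = nmb.max(axis=1, keepdims=True)
            is_best = nmb == best
            prob[i] = (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(strategies=list(psa.strategies), wtp=wtp,
                     probability=prob, mode=config.comparison_mode)


def _deltas(psa: PsaResult, intervention: str, control: str) -> Tuple[np.ndarray, np.ndarray]:
    i = psa.strategies.index(intervention)
    c = psa.strategies.index(control)
    return psa.costs[:, i] - psa.costs[:, c], psa.qalys[:, i] - psa.qalys[:, c]


def ne_quadrant_fraction(psa: PsaResult, intervention: str,
                         control: str = "waitlist") -> float:
    """Fraction of CE-plane draws that are both costlier and more effective."""
    dc, dq = _deltas(psa, intervention, control)
    return float(np.mean((dc > 0) & (dq > 0)))


def quadrant_fractions(psa: PsaResult, intervention: str,
                       control: str = "waitlist") -> Dict[str, float]:
    """All four CE-plane quadrant fractions (NE by strict inequality; axis
    draws fall to the adjacent non-NE quadrants; fractions sum to 1)."""
    dc, dq = _deltas(psa, intervention, control)
    ne = (dc > 0) & (dq > 0)
    se_ = (dc <= 0) & (dq > 0)
    nw = (dc > 0) & (dq <= 0)
    sw = (dc <= 0) & (dq <= 0)
    return {k: float(np.mean(v)) for k, v in
            (("NE", ne), ("SE", se_), ("NW", nw), ("SW", sw))}
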