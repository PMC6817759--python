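"""Synthetic three-arm trial generation and parameter estimation.

The cohort model consumes summary statistics of a randomized trial: the
per-arm proportion of women with a clinically significant improvement (a
0.5-SD change on the symptom scale, emulated here directly as a Bernoulli
responder flag), state-level mean utilities, and mean per-provider
healthcare costs.  This module simulates patient-level data with exactly
that structure — responder flags ~ binomial, utilities ~ moment-matched
beta, provider costs ~ gamma — and estimates a full parameter set back from
it, which makes end-to-end parameter-recovery testing possible without any
external data.

Patients are simulated cross-sectionally: a responder's utility and costs
are drawn from the reduced-symptoms state's distributions, a
non-responder's from the symptomatic state's.  Recurrence-state quantities
are not trial-observable and are copied from the template parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .parameters import ParameterSet, STRATEGIES

__all__ = ["TrialTruth", "TrialData", "simulate_trial",
           "estimate_parameter_set", "trial_to_frame", "trial_from_frame"]

_SE_FLOOR = 1e-6


def _default_cost_means() -> Dict[str, Dict[str, float]]:
    from .parameters import default_parameters

    return default_parameters().costs.provider_costs


@dataclass
class TrialTruth:
    """Ground truth of the simulated trial.

    Defaults mirror the source study's conditions: 254 women split over
    three arms (~85 each), response proportions 0.44/0.39/0.23, state mean
    utilities 0.83/0.85 with patient-level SDs implied by the reported
    standard errors at n = 85, and per-provider mean costs with a
    coefficient of variation matching a 20% standard error of the mean.
    """

    response_probs: Dict[str, float] = field(
        default_factory=lambda: {"guided": 0.44, "self_managed": 0.39, "waitlist": 0.23})
    utility_means: Dict[str, float] = field(
        default_factory=lambda: {"ms": 0.83, "red": 0.85})
    utility_sds: Dict[str, float] = field(
        default_factory=lambda: {"ms": 0.013 * 85 ** 0.5, "red": 0.017 * 85 ** 0.5})
    cost_means: Dict[str, Dict[str, float]] = field(default_factory=_default_cost_means)
    cost_cv: float = 0.20 * 85 ** 0.5  # per-patient coefficient of variation
    n_per_arm: int = 85
    seed: int = 0

    def validate(self) -> "TrialTruth":
        if any(not 0.0 <= p <= 1.0 for p in self.response_probs.values()):
            raise ValueError("response probabilities must be in [0, 1]")
        if any(sd < 0 for sd in self.utility_sds.values()):
            raise ValueError("utility sds must be >= 0")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        return self


@dataclass
class TrialData:
    """Patient-level synthetic trial data, one record set per arm."""

    arms: List[str]
    n: Dict[str, int]
    responders: Dict[str, int]
    responder_flags: Dict[str, np.ndarray]   # (n,) 0/1
    utilities: Dict[str, np.ndarray]         # (n,) in [0, 1]
    costs: Dict[str, pd.DataFrame]           # (n, categories), >= 0
    seed: int

    def validate(self) -> "TrialData":
        for arm in self.arms:
            if self.responders[arm] > self.n[arm]:
                raise ValueError(f"{arm}: responder count exceeds n")
            if ((self.utilities[arm] < 0) | (self.utilities[arm] > 1)).any():
                raise ValueError(f"{arm}: utilities outside [0, 1]")
            if (self.costs[arm].to_numpy() < 0).any():
                raise ValueError(f"{arm}: negative costs")
        return self


def _beta_draw(rng: np.random.Generator, mean: float, sd: float, size: int,
               label: str) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    if sd ** 2 >= mean * (1 - mean):
        raise ValueError(f"infeasible beta moments for state {label!r}: "
                         f"sd^2 >= mean*(1-mean)")
    nu = mean * (1 - mean) / sd ** 2 - 1
    return rng.beta(mean * nu, (1 - mean) * nu, size)


def simulate_trial(truth: TrialTruth) -> TrialData:
    """Draw one synthetic trial; reproducible given ``truth.seed``."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    arms = list(truth.response_probs)
    n = {arm: truth.n_per_arm for arm in arms}
    flags, utils, costs, responders = {}, {}, {}, {}
    cats_ms = truth.cost_means["menopausal_symptoms"]
    cats_red = truth.cost_means["reduction"]
    shape = 1.0 / truth.cost_cv ** 2 if truth.cost_cv > 0 else None
    for arm in arms:
        f = rng.binomial(1, truth.response_probs[arm], truth.n_per_arm)
        flags[arm] = f
        responders[arm] = int(f.sum())
        u = np.where(
            f == 1,
            _beta_draw(rng, truth.utility_means["red"], truth.utility_sds["red"],
                       truth.n_per_arm, "red"),
            _beta_draw(rng, truth.utility_means["ms"], truth.utility_sds["ms"],
                       truth.n_per_arm, "ms"),
        )
        utils[arm] = u
        cols = {}
        for cat in cats_ms:
            mean = np.where(f == 1, cats_red[cat], cats_ms[cat])
            if shape is None:
                cols[cat] = mean.astype(float)
            else:
                cols[cat] = rng.gamma(shape, mean / shape)
        costs[arm] = pd.DataFrame(cols)
    return TrialData(arms=arms, n=n, responders=responders, responder_flags=flags,
                     utilities=utils, costs=costs, seed=truth.seed).validate()


def estimate_parameter_set(data: TrialData, template: ParameterSet) -> ParameterSet:
    """Estimate a model parameter set from trial data.

    Response probabilities are per-arm responder fractions; state utilities
    and per-provider state costs are sample means pooled across arms by
    responder status, with standard errors of the mean written into the
    probabilistic specs (floored at a small epsilon for zero-variance
    categories).  Everything not observable in the trial is copied from the
    template.
    """
    data.validate()
    out = template.copy()
    for arm in data.arms:
        if data.n[arm] == 0:
            raise ValueError(f"{arm}: empty arm")
        out.transitions.p_response[arm] = data.responders[arm] / data.n[arm]
    all_flags = np.concatenate([data.responder_flags[a] for a in data.arms])
    all_utils = np.concatenate([data.utilities[a] for a in data.arms])
    all_costs = pd.concat([data.costs[a] for a in data.arms], ignore_index=True)
    for state, mask in (("ms", all_flags == 0), ("red", all_flags == 1)):
        n_state = int(mask.sum())
        if n_state == 0:
            continue
        u = all_utils[mask]
        mean = float(np.clip(u.mean(), 1e-9, 1 - 1e-9))
        se = max(float(u.std(ddof=1) / n_state ** 0.5), _SE_FLOOR)
        attr = f"u_{state}"
        setattr(out.utilities, attr, mean)
        spec = out.psa_specs.get(f"utilities.{attr}")
        if spec is not None:
            spec.mean = mean
            spec.se = min(se, (mean * (1 - mean)) ** 0.5 * 0.999)
        state_key = "menopausal_symptoms" if state == "ms" else "reduction"
        out.costs.provider_costs[state_key] = {
            cat: float(all_costs.loc[mask, cat].mean()) for cat in all_costs.columns
        }
    return out.validate()


def trial_to_frame(data: TrialData) -> pd.DataFrame:
    """Long-format export: arm, patient id, responder flag, utility, costs."""
    frames = []
    for arm in data.arms:
        df = data.costs[arm].copy()
        df.insert(0, "utility", data.utilities[arm])
        df.insert(0, "responder", data.responder_flags[arm])
        df.insert(0, "patient", np.arange(data.n[arm]))
        df.insert(0, "arm", arm)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def trial_from_frame(df: pd.DataFrame, seed: int = -1) -> TrialData:
    """Inverse of :func:`trial_to_frame`."""
    arms = list(dict.fromkeys(df["arm"]))
    cost_cols = [c for c in df.columns
                 if c not in ("arm", "patient", "responder", "utility")]
    n, responders, flags, utils, costs = {}, {}, {}, {}, {}
    for arm in arms:
        sub = df[df["arm"] == arm]
        n[arm] = len(sub)
        flags[arm] = sub["responder"].to_numpy()
        responders[arm] = int(flags[arm].sum())
        utils[arm] = sub["utility"].to_numpy()
        costs[arm] = sub[cost_cols].reset_index(drop=True)
    return TrialData(arms=arms, n=n, responders=responders, responder_flags=flags,
                     utilities=utils, costs=costs, seed=seed).validate()
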