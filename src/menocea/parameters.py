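"""Model inputs: loading, validation, and the built-in Dutch iCBT parameter set.

The parameter set drives a four-state Markov cohort model (menopausal
symptoms, reduction in menopausal symptoms, breast-cancer recurrence, death)
evaluating guided and self-managed Internet-based cognitive behavioral
therapy (iCBT) against a waiting-list control.  All quantities carry the
units stated on the dataclass fields; monetary values are EUR.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

STRATEGIES = ("guided", "self_managed", "waitlist")

__all__ = [
    "STRATEGIES",
    "DistributionSpec",
    "UtilitySet",
    "TransitionSpec",
    "CostSet",
    "BiaConfig",
    "ParameterSet",
    "ValidationError",
    "SchemaError",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "per_cycle_probability",
    "mortality_schedule",
]


class ValidationError(ValueError):
    """A parameter set violates one or more invariants."""


class SchemaError(ValueError):
    """A configuration file does not parse into the documented schema."""


def per_cycle_probability(annual_p: float, cycle_length: float) -> float:
    """Convert an annual transition probability to a per-cycle probability.

    Uses the constant-rate identity ``1 - (1 - p)**t`` with ``t`` the cycle
    length in years, so that compounding two half-year cycles recovers the
    annual probability exactly.
    """
    if not 0.0 <= annual_p <= 1.0:
        raise ValueError(f"annual probability must be in [0, 1], got {annual_p}")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    return 1.0 - (1.0 - annual_p) ** cycle_length


@dataclass
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    kind: "beta" (utilities, probabilities), "gamma" (costs),
    "dirichlet" (multinomial probabilities, via an effective sample size),
    or "fixed" (excluded from probabilistic analysis).
    """

    kind: str
    mean: float
    se: Optional[float] = None
    ess: Optional[float] = None

    def validate(self, name: str = "distribution") -> None:
        if self.kind not in {"beta", "gamma", "dirichlet", "fixed"}:
            raise ValidationError(f"{name}: unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ValidationError(f"{name}: beta mean must lie in (0, 1)")
            if self.se is not None and self.se ** 2 >= self.mean * (1.0 - self.mean):
                raise ValidationError(
                    f"{name}: beta se^2 must be < mean*(1-mean)"
                )
        elif self.kind == "gamma":
            if self.mean <= 0 or self.se is None or self.se <= 0:
                raise ValidationError(f"{name}: gamma requires mean > 0 and se > 0")
        elif self.kind == "dirichlet":
            if self.ess is None or self.ess <= 0:
                raise ValidationError(f"{name}: dirichlet requires ess > 0")


@dataclass
class UtilitySet:
    """Preference weights per health state (1 = full health, 0 = dead)."""

    u_ms: float = 0.83     # living with menopausal symptoms
    u_red: float = 0.85    # clinically significant symptom reduction
    u_rec: float = 0.73    # breast-cancer recurrence
    u_dead: float = 0.0

    def validate(self) -> List[str]:
        errors = []
        for name in ("u_ms", "u_red", "u_rec", "u_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"utilities.{name}: {v} outside [0, 1]")
        if self.u_dead != 0.0:
            errors.append("utilities.u_dead: must be 0")
        return errors


@dataclass
class TransitionSpec:
    """Transition probabilities of the cohort model.

    ``p_response`` is the first-cycle probability of moving from the
    symptomatic state to the reduced-symptoms state, per strategy — the
    trial's proportion of women with a clinically significant improvement
    (0.5 SD on the FACT-ES).  ``p_to_recurrence`` and ``p_rec_death`` are
    annual probabilities by default (``probs_are_annual``); background
    mortality is a schedule of annual probabilities spanning the cohort's
    ages over the model horizon.
    """

    p_response: Dict[str, float] = field(
        default_factory=lambda: {"guided": 0.44, "self_managed": 0.39, "waitlist": 0.23}
    )
    p_to_recurrence: float = 0.01
    p_rec_death: float = 0.04
    background_mortality: List[float] = field(
        default_factory=lambda: [0.0007, 0.0012]
    )
    probs_are_annual: bool = True
    mortality_is_per_cycle: bool = False

    def validate(self) -> List[str]:
        errors = []
        for strat, p in self.p_response.items():
            if not 0.0 <= p <= 1.0:
                errors.append(f"transitions.p_response.{strat}: {p} outside [0, 1]")
        for name in ("p_to_recurrence", "p_rec_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"transitions.{name}: {v} outside [0, 1]")
        bg = self.background_mortality
        if len(bg) < 1:
            errors.append("transitions.background_mortality: schedule is empty")
        if any(not 0.0 <= v <= 1.0 for v in bg):
            errors.append("transitions.background_mortality: values outside [0, 1]")
        if any(b < a for a, b in zip(bg, bg[1:])):
            errors.append(
                "transitions.background_mortality: must be non-decreasing with age"
            )
        return errors


@dataclass
class CostSet:
    """Per-state and intervention costs (EUR).

    ``provider_costs`` holds the mean per-cycle healthcare utilization cost
    for eight provider categories, separately for the symptomatic and the
    reduced-symptoms states.  In the source trial, utilization costs were
    *higher* after symptom reduction — the extra utilization was not
    attributable to the intervention itself, but it is what the cohort
    accrues.  Recurrence costs are per year, split over two tunnel cycles;
    beyond year 2 the default maintenance cost is zero (configurable via
    ``rec_post_fraction`` of the year-2 per-cycle cost).
    """

    intervention_cost: Dict[str, float] = field(
        default_factory=lambda: {"guided": 226.09, "self_managed": 47.92, "waitlist": 0.0}
    )
    provider_costs: Dict[str, Dict[str, float]] = field(default_factory=dict)
    recurrence_costs: Dict[str, Dict[str, float]] = field(default_factory=dict)
    rec_post_fraction: float = 0.0

    # -- derived sums -------------------------------------------------------
    @property
    def state_cost_ms(self) -> float:
        """EUR per cycle in the menopausal-symptoms state."""
        return float(sum(self.provider_costs.get("menopausal_symptoms", {}).values()))

    @property
    def state_cost_red(self) -> float:
        """EUR per cycle in the reduced-symptoms state."""
        return float(sum(self.provider_costs.get("reduction", {}).values()))

    @property
    def rec_year1_cost(self) -> float:
        """EUR per year during the first year of recurrence."""
        return float(sum(self.recurrence_costs.get("year1", {}).values()))

    @property
    def rec_year2_cost(self) -> float:
        """EUR per year during the second year of recurrence."""
        return float(sum(self.recurrence_costs.get("year2", {}).values()))

    @property
    def rec_post_cost(self) -> float:
        """EUR per cycle beyond the second year of recurrence."""
        return self.rec_post_fraction * self.rec_year2_cost / 2.0

    def scale_state_cost(self, state: str, target_sum: float) -> None:
        """Rescale one state's provider costs proportionally to a new total."""
        current = sum(self.provider_costs[state].values())
        if current <= 0:
            raise ValueError(f"cannot rescale zero-cost state {state!r}")
        f = target_sum / current
        self.provider_costs[state] = {
            k: v * f for k, v in self.provider_costs[state].items()
        }

    def validate(self) -> List[str]:
        errors = []
        for strat, v in self.intervention_cost.items():
            if v < 0:
                errors.append(f"costs.intervention_cost.{strat}: {v} < 0")
        g = self.intervention_cost.get("guided", 0.0)
        s = self.intervention_cost.get("self_managed", 0.0)
        if g <= s:
            errors.append("costs.intervention_cost: guided must exceed self_managed")
        if self.intervention_cost.get("waitlist", 0.0) != 0.0:
            errors.append("costs.intervention_cost.waitlist: must be 0")
        for state, cats in self.provider_costs.items():
            for cat, v in cats.items():
                if v < 0:
                    errors.append(f"costs.provider_costs.{state}.{cat}: {v} < 0")
        for year, items in self.recurrence_costs.items():
            for cat, v in items.items():
                if v < 0:
                    errors.append(f"costs.recurrence_costs.{year}.{cat}: {v} < 0")
        if self.rec_post_fraction < 0:
            errors.append("costs.rec_post_fraction: must be >= 0")
        return errors


@dataclass
class BiaConfig:
    """Budget-impact configuration: annual treated population and uptake mix."""

    annual_population: int = 600
    mix_weights: Dict[str, float] = field(
        default_factory=lambda: {"guided": 0.5, "self_managed": 0.5}
    )

    def validate(self) -> List[str]:
        errors = []
        if self.annual_population < 0:
            errors.append("bia.annual_population: must be >= 0")
        if any(not 0.0 <= w <= 1.0 for w in self.mix_weights.values()):
            errors.append("bia.mix_weights: weights outside [0, 1]")
        if abs(sum(self.mix_weights.values()) - 1.0) > 1e-9:
            errors.append("bia.mix_weights: weights must sum to 1")
        return errors


@dataclass
class ParameterSet:
    """Complete input set for the cohort model and its economic evaluation."""

    utilities: UtilitySet = field(default_factory=UtilitySet)
    transitions: TransitionSpec = field(default_factory=TransitionSpec)
    costs: CostSet = field(default_factory=CostSet)
    bia: BiaConfig = field(default_factory=BiaConfig)
    psa_specs: Dict[str, DistributionSpec] = field(default_factory=dict)
    discount_effects: float = 0.015  # annual rate on QALYs
    discount_costs: float = 0.04     # annual rate on costs
    cycle_length: float = 0.5        # years
    n_cycles: int = 10
    cohort_size: int = 1000
    baseline_age: float = 47.0
    wtp: float = 30_000.0            # EUR per QALY
    effect_duration_cycles: Optional[int] = None  # None => full horizon
    cost_se_fraction: float = 0.20   # "±20%" rule for cost standard errors
    # accrual timing: occupancy counted at cycle start ("begin"), end
    # ("end"), or averaged with mid-cycle discounting ("half_cycle")
    accrual: str = "begin"
    response_before_competing_risks: bool = False

    def validate(self) -> "ParameterSet":
        """Check every invariant; raise ValidationError listing all breaches."""
        errors = []
        errors += self.utilities.validate()
        errors += self.transitions.validate()
        errors += self.costs.validate()
        errors += self.bia.validate()
        for name, spec in self.psa_specs.items():
            try:
                spec.validate(f"psa_specs.{name}")
            except ValidationError as exc:
                errors.append(str(exc))
        if self.n_cycles < 1:
            errors.append(f"n_cycles: {self.n_cycles} < 1")
        if self.cycle_length <= 0:
            errors.append(f"cycle_length: {self.cycle_length} <= 0")
        for name in ("discount_effects", "discount_costs"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                errors.append(f"{name}: {r} outside [0, 1)")
        if self.cohort_size < 1:
            errors.append(f"cohort_size: {self.cohort_size} < 1")
        if self.effect_duration_cycles is not None and not (
            1 <= self.effect_duration_cycles <= self.n_cycles
        ):
            errors.append(
                f"effect_duration_cycles: {self.effect_duration_cycles} "
                f"outside [1, n_cycles]"
            )
        if self.accrual not in {"begin", "end", "half_cycle"}:
            errors.append(f"accrual: unknown mode {self.accrual!r}")
        if not 0.0 <= self.cost_se_fraction < 1.0:
            errors.append(f"cost_se_fraction: {self.cost_se_fraction} outside [0, 1)")
        if errors:
            raise ValidationError("; ".join(errors))
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psa_specs"] = {k: asdict(v) for k, v in self.psa_specs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = copy.deepcopy(d)
        try:
            specs = {
                k: DistributionSpec(**v) for k, v in d.pop("psa_specs", {}).items()
            }
            obj = cls(
                utilities=UtilitySet(**d.pop("utilities", {})),
                transitions=TransitionSpec(**d.pop("transitions", {})),
                costs=CostSet(**d.pop("costs", {})),
                bia=BiaConfig(**d.pop("bia", {})),
                psa_specs=specs,
                **d,
            )
        except TypeError as exc:
            raise SchemaError(f"unrecognized or missing configuration key: {exc}") from exc
        return obj


def mortality_schedule(transitions: TransitionSpec, n_cycles: int,
                       cycle_length: float = 0.5) -> List[float]:
    """Per-cycle background mortality over the model horizon.

    The schedule's endpoints are annual probabilities at the cohort's
    baseline and final ages; intermediate annual values are linearly
    interpolated (one value per model year, reused for both 6-month cycles
    of that year), then converted to per-cycle probabilities unless the
    schedule is flagged as already per cycle.
    """
    bg = transitions.background_mortality
    cycles_per_year = max(int(round(1.0 / cycle_length)), 1)
    n_years = math.ceil(n_cycles / cycles_per_year)
    if len(bg) == n_years:
        annual = list(bg)
    else:
        lo, hi = bg[0], bg[-1]
        if n_years == 1:
            annual = [lo]
        else:
            annual = [lo + (hi - lo) * i / (n_years - 1) for i in range(n_years)]
    out = []
    for c in range(n_cycles):
        a = annual[c // cycles_per_year]
        if transitions.mortality_is_per_cycle:
            out.append(a)
        else:
            out.append(per_cycle_probability(a, cycle_length))
    return out


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter configuration from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: cannot parse configuration: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return ParameterSet.from_dict(raw).validate()


def save_parameters(params: ParameterSet, path) -> None:
    """Write a parameter set back to YAML or JSON; round-trips exactly."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def default_parameters() -> ParameterSet:
    """The built-in parameter set of the Dutch iCBT evaluation.

    Loaded from the packaged ``dutch_icbt.yaml`` configuration: trial-derived
    utilities and response proportions, Dutch registry transition
    probabilities, per-provider healthcare costs, and intervention costs
    including 44% overhead.
    """
    ref = resources.files("menocea").joinpath("data/dutch_icbt.yaml")
    raw = yaml.safe_load(ref.read_text())
    return ParameterSet.from_dict(raw).validate()
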