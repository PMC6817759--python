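"""Result rendering: command-style entry points that tie the pipeline
together, write CSV/JSON artifacts, and record a run manifest.

Each ``cmd_*`` function is the programmatic equivalent of a pipeline step
(deterministic evaluation, PSA, tornado, NNT panel, trial simulation).  The
analysis drivers under ``analysis/`` call these.  Every output set is
accompanied by a ``manifest.json`` recording the command, configuration
hash, seed, and written files, which suffices to reproduce the outputs:
deterministic ones bit-identically, stochastic ones identically given the
recorded seed.  Monetary values are written unrounded and without currency
symbols; units live in column headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .econ import cost_per_responder, deterministic_table, nnt_from_probabilities
from .markov import run_cohort
from .parameters import ParameterSet, load_parameters, save_parameters
from .psa import PsaConfig, ceac, ne_quadrant_fraction, quadrant_fractions, run_psa
from .sensitivity import run_scenario, tornado, tornado_frame
from .trial import TrialTruth, simulate_trial, trial_to_frame

log = logging.getLogger("menocea")

__all__ = ["RunManifest", "cmd_run", "cmd_psa", "cmd_tornado", "cmd_nnt",
           "cmd_simulate_trial"]


@dataclass
class RunManifest:
    command: str
    config: Optional[str]
    config_sha256: Optional[str]
    seed: Optional[int]
    timestamp: str
    version: str
    outputs: List[str] = field(default_factory=list)

    def write(self, outdir: Path) -> Path:
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2))
        return path


def _resolve_params(config) -> tuple[ParameterSet, Optional[str], Optional[str]]:
    if isinstance(config, ParameterSet):
        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        return config, None, hashlib.sha256(blob).hexdigest()
    params = load_parameters(config)
    digest = hashlib.sha256(Path(config).read_bytes()).hexdigest()
    return params, str(config), digest


def _start(command: str, config, seed: Optional[int]) -> tuple[ParameterSet, RunManifest]:
    params, cfg_path, digest = _resolve_params(config)
    manifest = RunManifest(
        command=command, config=cfg_path, config_sha256=digest, seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(), version=__version__)
    return params, manifest


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    manifest.outputs.append(str(path))
    log.info("wrote %s (%d rows, config %s, seed %s)",
             path, len(df), manifest.config_sha256, manifest.seed)


def cmd_run(config, perspective: str = "healthcare", output_dir="results/run",
            scenarios: Sequence[str] = ("base_case",)) -> Dict[str, pd.DataFrame]:
    """Deterministic evaluation: strategy totals, increments, ICURs, budget
    impact, plus the cohort traces, for each requested scenario."""
    params, manifest = _start("run", config, seed=None)
    outdir = Path(output_dir)
    tables = []
    for name in scenarios:
        bundle = run_scenario(params, name)
        t = bundle["table"].copy()
        t.insert(0, "scenario", name)
        mix = bundle["bia_mix"]
        t.loc[len(t)] = {"scenario": name, "strategy": mix.strategy_or_mix,
                         "perspective": mix.perspective,
                         "bia_eur_per_year": mix.annual_budget_impact}
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    if perspective == "intervention" and "intervention_perspective" not in scenarios:
        raise ValueError("use the intervention_perspective scenario")
    traces = pd.concat(
        [run_cohort(params, s).to_frame() for s in params.transitions.p_response],
        ignore_index=True)
    _write(table, outdir / "deterministic_results.csv", manifest)
    _write(traces, outdir / "cohort_traces.csv", manifest)
    manifest.write(outdir)
    return {"table": table, "traces": traces}


def cmd_psa(config, n_draws: int = 5000, seed: int = 0,
            wtp_grid: Optional[Sequence[float]] = None,
            perspective: str = "healthcare",
            output_dir="results/psa") -> Dict[str, object]:
    """Probabilistic analysis: draw matrix, pairwise and multiway CEACs, and
    CE-plane quadrant fractions."""
    params, manifest = _start("psa", config, seed=seed)
    outdir = Path(output_dir)
    cfg = PsaConfig(n_draws=n_draws, seed=seed, perspective=perspective)
    if wtp_grid is not None:
        cfg.wtp_grid = list(wtp_grid)
    psa = run_psa(params, cfg)
    draws = psa.to_frame()
    ctrl = cfg.control
    pair = ceac(psa, cfg).to_frame()
    multi_cfg = PsaConfig(**{**cfg.__dict__, "comparison_mode": "multiway"})
    multi = ceac(psa, multi_cfg).to_frame()
    quad_rows = []
    for s in psa.strategies:
        if s == ctrl:
            continue
        q = quadrant_fractions(psa, s, ctrl)
        quad_rows.append({"strategy": s, **q})
    quads = pd.DataFrame(quad_rows)
    _write(draws, outdir / "psa_draws.csv", manifest)
    _write(pair, outdir / "ceac_pairwise.csv", manifest)
    _write(multi, outdir / "ceac_multiway.csv", manifest)
    _write(quads, outdir / "ce_plane_quadrants.csv", manifest)
    manifest.write(outdir)
    return {"psa": psa, "ceac_pairwise": pair, "ceac_multiway": multi,
            "quadrants": quads}


def cmd_tornado(config, strategy: str = "guided",
                output_dir="results/tornado") -> pd.DataFrame:
    """One-way sensitivity analyses ranked by ICUR swing."""
    params, manifest = _start("tornado", config, seed=None)
    rows = tornado_frame(tornado(params, strategy))
    rows.insert(0, "strategy", strategy)
    _write(rows, Path(output_dir) / f"tornado_{strategy}.csv", manifest)
    manifest.write(Path(output_dir))
    return rows


def cmd_nnt(config, endpoint_probs: Optional[Dict[str, Dict[str, float]]] = None,
            nnt_overrides: Optional[Dict[str, Dict[str, float]]] = None,
            output_dir="results/nnt") -> pd.DataFrame:
    """Cost-per-responder panel.

    ``endpoint_probs`` maps endpoint -> strategy -> response probability;
    NNTs are 1/ARR versus the waitlist.  ``nnt_overrides`` (endpoint ->
    strategy -> NNT) takes precedence, for NNTs computed on unrounded trial
    proportions.  Incremental costs come from the deterministic model under
    both the healthcare and the intervention perspective.
    """
    params, manifest = _start("nnt", config, seed=None)
    if endpoint_probs is None:
        endpoint_probs = {"FACT-ES": dict(params.transitions.p_response)}
    nnt_overrides = nnt_overrides or {}
    dc = {}
    for persp in ("healthcare", "intervention"):
        t = deterministic_table(params, persp).set_index("strategy")
        dc[persp] = t["delta_cost_eur"]
    rows = []
    for endpoint, probs in endpoint_probs.items():
        for s, p in probs.items():
            if s == "waitlist":
                continue
            override = nnt_overrides.get(endpoint, {}).get(s)
            if override is not None:
                nnt_value, arr = override, 1.0 / override
            else:
                res = nnt_from_probabilities(p, probs["waitlist"])
                if res.no_benefit:
                    rows.append({"endpoint": endpoint, "strategy": s,
                                 "arr": res.arr, "nnt": None})
                    continue
                nnt_value, arr = res.nnt, res.arr
            rows.append({
                "endpoint": endpoint, "strategy": s, "arr": arr, "nnt": nnt_value,
                "delta_cost_healthcare_eur": dc["healthcare"][s],
                "delta_cost_intervention_eur": dc["intervention"][s],
                "cost_per_responder_healthcare_eur":
                    cost_per_responder(nnt_value, dc["healthcare"][s]),
                "cost_per_responder_intervention_eur":
                    cost_per_responder(nnt_value, dc["intervention"][s]),
            })
    df = pd.DataFrame(rows)
    _write(df, Path(output_dir) / "nnt_cost_per_responder.csv", manifest)
    manifest.write(Path(output_dir))
    return df


def cmd_simulate_trial(truth: Optional[TrialTruth] = None, seed: int = 0,
                       output_dir="results/trial") -> pd.DataFrame:
    """Simulate one synthetic three-arm trial and export it long-format."""
    truth = truth or TrialTruth(seed=seed)
    truth.seed = seed
    manifest = RunManifest(command="simulate-trial", config=None,
                           config_sha256=None, seed=seed,
                           timestamp=datetime.now(timezone.utc).isoformat(),
                           version=__version__)
    df = trial_to_frame(simulate_trial(truth))
    _write(df, Path(output_dir) / "synthetic_trial.csv", manifest)
    manifest.write(Path(output_dir))
    return df
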