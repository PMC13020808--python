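"""End-to-end orchestration: design -> simulate -> score -> fit -> report.

A :class:`RunConfig` fully determines a run; saved to YAML/JSON it re-runs
bit-identically for the deterministic stages and draw-identically for the
seeded stochastic ones.  Each stage writes CSV outputs plus a manifest JSON
recording the config, seeds, package version and file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import CohortDistribution, simulate_cohort
from .design import (
    PerformanceConfig,
    annotate_trials,
    assign_blocks,
    experiment_layout,
    generate_number_list,
    generate_stimulus_list,
)
from .metrics import condition_summary, self_allocation_bias
from .model import ZOIBModel

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "DEFAULT_ANALYSES"]

#: The five standard analyses: name -> (formula, response source).
#: Analyses 1-3 model relative allocation; 4-5 model the matched bias.
DEFAULT_ANALYSES = {
    "analysis-1": ("relative_allocation ~ self_relevance * criterion + (1|participant_id)", "records"),
    "analysis-2": ("relative_allocation ~ self_relevance * criterion * svo_z + (1|participant_id)", "records"),
    "analysis-3": ("relative_allocation ~ relative_performance * self_relevance"
                   " + relative_performance * criterion + (1|participant_id)", "records"),
    "analysis-4": ("bias ~ contribution_category + (1|participant_id)", "bias"),
    "analysis-5": ("bias ~ contribution_category * svo_z + (1|participant_id)", "bias"),
}


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    experiment: str = "exp2"
    seed: int = 0
    n_participants: int = 20
    engine: str = "laplace"
    analyses: tuple[str, ...] = tuple(DEFAULT_ANALYSES)
    loss_fraction: float = 0.2
    miss_rate: float = 0.0096
    bias_gating: str = "recipient"
    null_cohort: bool = False
    n_draws: int = 2000
    out_dir: str = "runs/latest"

    _KNOWN = None  # filled below

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "analyses" in d:
            bad = set(d["analyses"]) - set(DEFAULT_ANALYSES)
            if bad:
                raise ValueError(f"unknown analysis name(s): {sorted(bad)}")
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(d["analyses"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "stages": {}, "files": {}}
    t_all = time.time()

    def stage(name):
        log(f"[{name}] ...")
        manifest["stages"][name] = {"started": time.time() - t_all}

    def done(name, *paths):
        manifest["stages"][name]["seconds"] = round(
            time.time() - t_all - manifest["stages"][name]["started"], 3)
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    layout = experiment_layout(config.experiment)
    perf_cfg = PerformanceConfig(loss_fraction=config.loss_fraction)

    stage("design")
    numbers = generate_number_list(config.seed)
    stimuli = generate_stimulus_list(layout, perf_cfg, seed=config.seed)
    trial_table = annotate_trials(assign_blocks(layout, stimuli, seed=config.seed))
    p_numbers = out / "number_list.csv"
    p_trials = out / "trials.csv"
    _write(numbers.to_frame(), p_numbers)
    _write(trial_table, p_trials)
    done("design", p_numbers, p_trials)

    stage("simulate")
    dist = CohortDistribution.null() if config.null_cohort else CohortDistribution()
    records, truth = simulate_cohort(
        config.n_participants, dist, layout, seed=config.seed,
        perf_config=perf_cfg, stimuli=stimuli,
        bias_gating=config.bias_gating, miss_rate=config.miss_rate,
    )
    p_records = out / "cohort_records.csv"
    p_truth = out / "cohort_truth.csv"
    _write(records, p_records)
    _write(truth, p_truth)
    done("simulate", p_records, p_truth)

    stage("score")
    bias, n_unmatched = self_allocation_bias(records)
    summary = condition_summary(records)
    p_bias = out / "bias_table.csv"
    p_summary = out / "condition_summary.csv"
    _write(bias, p_bias)
    _write(summary, p_summary)
    manifest["stages"]["score"]["unmatched_stimuli"] = n_unmatched
    done("score", p_bias, p_summary)

    stage("fit")
    fit_paths = []
    for name in config.analyses:
        formula, source = DEFAULT_ANALYSES[name]
        data = records if source == "records" else bias
        res = ZOIBModel.from_formula(formula, data).fit(
            engine=config.engine, seed=config.seed, n_draws=config.n_draws)
        p_fit = out / f"{name}_summary.csv"
        _write(res.summary(), p_fit)
        fit_paths.append(p_fit)
        manifest["stages"]["fit"][name] = {"converged": res.converged}
        if name == "analysis-2":
            mm = res.marginal_means(["self_relevance", "criterion"])
            p_c = out / f"{name}_contrasts.csv"
            _write(mm.contrasts, p_c)
            fit_paths.append(p_c)
    done("fit", *fit_paths)

    stage("report")
    p_manifest = out / "manifest.json"
    done("report")
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    p_manifest.write_text(json.dumps(manifest, indent=2))
    log(f"run complete in {manifest['total_seconds']} s -> {out}")
    return manifest


def make_fixtures(seed: int = 0, out_dir: Optional[str] = None):
    """Small packaged datasets for tests and demos.

    Returns (stimulus list, 6-participant cohort records, truth table, SVO
    option-index fixtures); writes CSVs when ``out_dir`` is given.
    """
    layout = experiment_layout("exp2")
    stimuli = generate_stimulus_list(layout, seed=seed)
    records, truth = simulate_cohort(6, CohortDistribution(), layout, seed=seed,
                                     stimuli=stimuli)
    svo_fixture = pd.DataFrame(
        {"participant_id": [f"p{i:03d}" for i in range(6)],
         **{f"item{j+1}": np.random.default_rng(seed + j).integers(0, 9, 6)
            for j in range(6)}}
    )
    if out_dir is not None:
        out = Path(out_dir)
        _write(stimuli.to_frame(), out / "fixture_trials.csv")
        _write(records, out / "fixture_cohort.csv")
        _write(truth, out / "fixture_truth.csv")
        _write(svo_fixture, out / "fixture_svo.csv")
    return stimuli, records, truth, svo_fixture
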