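"""End-to-end pipeline: load or simulate the two tables, build the cohort,
run the stepwise and direct merges, evaluate, and write artifacts.

Config is a single YAML/JSON mapping with blocks::

    inputs:            # either this ...
      trial: trial.csv
      admin: admin.csv
      truth: truth.csv        # optional, enables evaluation
    simulate:          # ... or this (SimConfig fields; seed may be overridden)
      n_trial: 415
    cohort_window: {start: "2006-08-14", end: "2010-06-15"}
    steps: steps.yaml         # or an inline list of step dicts
    direct: true              # also run the direct merge + concordance
    outputs: {dir: out}
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .cohort import derive_index_records, filter_aml_cohort
from .concordance import concordance, evaluate_against_truth
from .errors import ConfigError, SteplinkError
from .io import (
    read_admin_table,
    read_trial_table,
    read_truth_links,
    write_admin_table,
    write_trial_table,
    write_truth_links,
)
from .matching import DirectLinkage, StepwiseLinkage
from .reporting import report_dict, step_summary
from .simulate import SimConfig, simulate_pair
from .steps import DEFAULT_STEPS, load_steps, steps_from_config

__all__ = ["load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


def load_config(path: Union[str, Path]) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return data


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SteplinkError as exc:
                raise type(exc)(f"[stage: {name}] {exc}") from exc

        return wrapped

    return deco


def _sim_config(block: dict, seed: Optional[int]) -> SimConfig:
    kwargs = dict(block)
    if "window" in kwargs:
        kwargs["window"] = tuple(_dt.date.fromisoformat(d) for d in kwargs["window"])
    for key in ("admission_lag_days", "birth_year_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    valid = {f.name for f in dataclass_fields(SimConfig)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
    return SimConfig(**kwargs)


def run_pipeline(
    config: dict,
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> dict:
    """Execute the full pipeline; returns the report dict.

    Writes into ``out_dir``: the matches CSV, aligned-text and TSV summary
    tables, the JSON report, and a run log (plus the simulated tables when
    a ``simulate`` block is used). Any stage failure aborts with a
    stage-tagged error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if "simulate" in config:
        sim_cfg = _stage("simulate")(_sim_config)(config["simulate"], seed)
        trial, admissions, truth = _stage("simulate")(simulate_pair)(sim_cfg)
        write_trial_table(trial, out / "trial.csv")
        write_admin_table(admissions, out / "admin.csv")
        write_truth_links(truth, out / "truth.csv")
        window = sim_cfg.window
        seed_used = sim_cfg.seed
    elif "inputs" in config:
        inputs = config["inputs"]
        trial = _stage("load")(read_trial_table)(inputs["trial"])
        admissions = _stage("load")(read_admin_table)(inputs["admin"])
        if inputs.get("truth"):
            truth = _stage("load")(read_truth_links)(inputs["truth"])
        window = None
        if "cohort_window" in config:
            cw = config["cohort_window"]
            window = (
                _dt.date.fromisoformat(str(cw["start"])),
                _dt.date.fromisoformat(str(cw["end"])),
            )
        seed_used = seed
    else:
        raise ConfigError("config needs an 'inputs' or a 'simulate' block")

    if window is not None:
        admissions = _stage("cohort-filter")(filter_aml_cohort)(admissions, window)
    index = _stage("index-derivation")(derive_index_records)(admissions)

    steps_cfg = config.get("steps")
    if steps_cfg is None:
        steps = DEFAULT_STEPS
    elif isinstance(steps_cfg, (str, Path)):
        steps = _stage("steps")(load_steps)(steps_cfg)
    else:
        steps = _stage("steps")(steps_from_config)(steps_cfg)

    result = _stage("stepwise-match")(StepwiseLinkage(trial, index, steps).fit)()
    for sr in result.step_results:
        hist: dict[int, int] = {}
        for ids in sr.candidate_ids.values():
            hist[len(ids)] = hist.get(len(ids), 0) + 1
        logger.info(
            "step %d candidate-count histogram: %s", sr.step_number, dict(sorted(hist.items()))
        )

    direct_res = None
    summaries = []
    if config.get("direct", True):
        direct_res = _stage("direct-match")(lambda: DirectLinkage(trial, index).fit())()
        summaries = [
            _stage("concordance")(concordance)(result, direct_res, "C1"),
            _stage("concordance")(concordance)(result, direct_res, "C2"),
        ]

    evaluation = None
    if truth is not None:
        evaluation = _stage("evaluate")(evaluate_against_truth)(result, truth)

    report = report_dict(
        result, concordance=summaries, evaluation=evaluation, direct=direct_res, seed=seed_used
    )
    table = step_summary(result, concordance=summaries)

    result.to_matches_frame().to_csv(out / "matches.csv", index=False)
    (out / "summary.txt").write_text(table.to_text() + "\n")
    (out / "summary.tsv").write_text(table.to_tsv())
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "run.log").write_text(
        f"steplink {__version__}\nseed: {seed_used}\nsteps: {len(steps)}\n"
        f"n_trial: {len(trial)}\nn_admin_patients: {len(index)}\n"
    )
    return report
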