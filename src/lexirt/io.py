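"""File formats, run configuration, and the end-to-end orchestrator.

Tabular data are UTF-8 comma-delimited CSV with a header; models, configs,
ledgers and reports are JSON.  Every run directory is self-describing: it
contains the resolved configuration, a JSON-lines event log with per-stage
counts, and a manifest of SHA-256 hashes so identical configurations can be
verified to produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import irt, psych, rt, selection, synthetic
from .synthetic import RESPONSE_COLUMNS, RTGenParams, SessionDesign

logger = logging.getLogger("lexirt")

__all__ = ["RunConfig", "read_responses", "write_responses", "read_item_bank",
           "write_item_bank", "read_cohort", "write_cohort", "end_to_end"]

_FLOAT_FMT = "%.12g"


def write_responses(responses: pd.DataFrame, path):
    responses.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_responses(path) -> pd.DataFrame:
    """Read and validate a long-format response CSV.

    Requires the declared header; extra columns are preserved.  Schema
    violations are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response file missing columns: {sorted(missing)}")
    bad = df.index[~df["correct"].isin((0, 1))]
    if len(bad):
        raise ValueError(f"correct must be 0/1; first bad row: {bad[0] + 1}")
    bad = df.index[~(df["rt_seconds"] > 0) | ~np.isfinite(df["rt_seconds"])]
    if len(bad):
        raise ValueError(f"rt_seconds must be positive and finite; first bad row: {bad[0] + 1}")
    dup = df.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (person_id, item_id) pair at row {int(np.flatnonzero(dup)[0]) + 1}")
    for col in ("block_index", "trial_index"):
        bad = df.index[df[col] < 1]
        if len(bad):
            raise ValueError(f"{col} must be 1-based; first bad row: {bad[0] + 1}")
    return df


def write_item_bank(items: pd.DataFrame, path):
    items.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_item_bank(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(synthetic.ITEM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"item bank missing columns: {sorted(missing)}")
    return df


def write_cohort(cohort: pd.DataFrame, path):
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(synthetic.COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end run.

    Stage thresholds default to the published pipeline settings: correlation
    screen r > 0.10, Rasch fit window [0.6, 1.4], 2PL slope floor 0.7, three
    lists, RT window [0.2 s, 5 s], IQR fence multiplier 3, and a one-sided
    3-sd participant screen on median RT.
    """

    seed: int = 0
    n_real: int = 250
    n_pseudo: int = 250
    n_persons: int = 120
    n_blocks: int = 5
    real_per_block: int = 50
    pseudo_per_block: int = 50
    difficulty_spread: tuple = (-3.0, 3.0)
    planted_bad_fraction: float = 0.0
    noncompliant_fraction: float = 0.0
    missing_criterion_fraction: float = 0.0
    criterion_noise_sd: float = 4.4
    r_threshold: float = 0.10
    screen_rule: str = "either"
    fit_range: tuple = (0.6, 1.4)
    a_min: float = 0.7
    n_lists: int = 3
    rt_min_s: float = 0.2
    rt_max_s: float = 5.0
    iqr_multiplier: float = 3.0
    participant_sd: float = 3.0
    quadrature_nodes: int = 61

    def to_json(self, path=None) -> str:
        obj = dataclasses.asdict(self)
        obj["difficulty_spread"] = list(self.difficulty_spread)
        obj["fit_range"] = list(self.fit_range)
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            obj = json.loads(Path(source).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("difficulty_spread", "fit_range"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _EventLog:
    def __init__(self, path: Path):
        self.path = path
        self.events = []

    def log(self, stage: str, **counts):
        event = {"stage": stage, **counts}
        self.events.append(event)
        logger.info("stage %s: %s", stage, counts)

    def flush(self):
        with open(self.path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e, sort_keys=True) + "\n")


def end_to_end(config: RunConfig, out_dir) -> dict:
    """Simulate, screen, select, assemble, evaluate and report in one run.

    Writes all artifacts plus a manifest of their SHA-256 hashes to
    ``out_dir`` and returns the manifest dictionary.  The run is fully
    determined by the configuration (including its seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = _EventLog(out / "events.jsonl")
    config.to_json(out / "config.json")

    bank = synthetic.generate_item_bank(
        config.n_real, config.n_pseudo,
        difficulty_spread=config.difficulty_spread,
        planted_bad_fraction=config.planted_bad_fraction, seed=config.seed)
    cohort = synthetic.generate_cohort(
        config.n_persons, criterion_noise_sd=config.criterion_noise_sd,
        missing_criterion_fraction=config.missing_criterion_fraction,
        noncompliant_fraction=config.noncompliant_fraction, seed=config.seed)
    design = SessionDesign(n_blocks=config.n_blocks,
                           real_per_block=config.real_per_block,
                           pseudo_per_block=config.pseudo_per_block)
    responses = synthetic.simulate_session(bank, cohort, design, seed=config.seed)
    write_item_bank(bank, out / "item_bank.csv")
    write_cohort(cohort, out / "cohort.csv")
    write_responses(responses, out / "responses.csv")
    events.log("simulate", n_items=len(bank), n_persons=len(cohort),
               n_trials=len(responses))

    kept, person_ledger = rt.exclude_outlier_participants(
        responses, n_sd=config.participant_sd)
    events.log("exclude_participants",
               n_excluded=len(person_ledger.excluded_persons),
               n_trials_in=person_ledger.n_input_trials,
               n_trials_out=person_ledger.n_retained_trials)

    criterion = cohort.set_index("person_id")["criterion_observed"]
    result = selection.run_selection_pipeline(
        kept, criterion, r_threshold=config.r_threshold, rule=config.screen_rule,
        fit_range=config.fit_range, a_min=config.a_min,
        quadrature_nodes=config.quadrature_nodes)
    with open(out / "selection_reports.jsonl", "w") as fh:
        for rep in result.reports:
            fh.write(json.dumps(rep.to_dict(), sort_keys=True) + "\n")
    result.rasch_model.to_json(out / "rasch_model.json")
    result.twopl_model.to_json(out / "twopl_model.json")
    for rep in result.reports:
        events.log(rep.step_label, n_removed=len(rep.removed),
                   n_retained=len(rep.retained), n_iterations=rep.n_iterations)

    retained = result.retained_table(bank)
    lists = selection.assemble_lists(retained, n_lists=config.n_lists,
                                     seed=config.seed)
    lists.assignment()[["list_id", "item_id", "lexicality", "length", "b_hat"]].to_csv(
        out / "stimulus_lists.csv", index=False, float_format=_FLOAT_FMT)
    events.log("assemble", **{f"n_{k}": v for k, v in lists.sizes().items()})

    evaluation = selection.evaluate_lists(lists, result.rasch_model, kept)
    abilities = irt.estimate_abilities(result.rasch_model, kept)
    reliability = irt.marginal_reliability(result.rasch_model, abilities)
    scores = psych.accuracy_scores(kept, items=bank,
                                   list_assignment=lists.assignment())
    scores.to_csv(out / "scores.csv", float_format=_FLOAT_FMT)
    r_acc, n_acc = psych.criterion_correlation(scores["overall"], criterion)

    rt_filtered, trial_ledger = rt.filter_rt_trials(
        kept, min_s=config.rt_min_s, max_s=config.rt_max_s,
        iqr_multiplier=config.iqr_multiplier)
    events.log("filter_rt", **trial_ledger.excluded_trials)
    effects = rt.estimate_rt_effects(
        rt_filtered, bank, cohort,
        model_terms=("lexicality", "log_frequency", "bigram_pseudo", "length",
                     "length_x_ability"))
    effects.to_csv(out / "rt_effects.csv", index=False, float_format=_FLOAT_FMT)

    report = {
        "n_items_retained": len(result.retained_items),
        "removals_per_step": {rep.step_label: len(rep.removed)
                              for rep in result.reports},
        "list_sizes": lists.sizes(),
        "list_class_counts": lists.class_counts().to_dict(),
        "list_difficulty_means": {k: float(v) for k, v in
                                  lists.difficulty_summary()["mean"].items()},
        "info_ratio_range": list(evaluation.info_ratio_range),
        "icc_single": evaluation.icc_single,
        "icc_average": evaluation.icc_average,
        "marginal_reliability": reliability,
        "accuracy_criterion_r": r_acc,
        "accuracy_criterion_n": n_acc,
        "rt_trial_exclusion_fraction": trial_ledger.fraction_excluded,
        "excluded_participants": [p for p, _, _ in person_ledger.excluded_persons],
    }
    if config.planted_bad_fraction > 0:
        planted = set(bank.loc[bank["pathology"] != "none", "item_id"])
        removed_23 = {i for rep in result.reports[1:] for i in rep.removed_ids}
        clean = set(bank["item_id"]) - planted
        step1_kept = set(result.reports[0].retained)
        report["planted_recall"] = {
            "n_planted": len(planted),
            "planted_removed_steps23": len(planted & removed_23),
            "recall_steps23": len(planted & removed_23) / max(len(planted & step1_kept), 1),
            "clean_retention": len(clean & set(result.retained_items)) / len(clean),
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    events.flush()

    manifest = {"seed": config.seed, "files": {}}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
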