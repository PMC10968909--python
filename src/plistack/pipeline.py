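"""Staged, resumable pipeline: simulate → features → tune → select →
evaluate → report.

Every stage writes its outputs plus a small manifest (configuration hash,
seed, package version) into the run directory; a stage whose manifest
matches the current configuration is skipped on re-run, so runs are
resumable and deterministic end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import split_feature_table
from .edf import read_cohort, write_cohort
from .experiments import cohort_features, rhythm_experiments, window_sweep
from .metrics import compare_models
from .models import DEFAULT_N_ESTIMATORS, DEFAULT_N_TRIALS, MODEL_NAMES, tune
from .report import count_per_rhythm, edge_list, region_strength
from .selection import build_full_index, select_optimal_subset
from .synthetic import default_templates, generate_cohort

log = logging.getLogger("plistack")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Defaults mirror the study-scale settings (windows 2-16 s, analysis
    window 12 s, ranking p=100/k=5, evaluation p=5/k=5, 30 tuning trials);
    scale the cohort and these knobs down for desk-scale runs.
    """

    out_dir: str = "run"
    edf_dir: str | None = None          # real-data entry point; None → simulate
    n_subjects: tuple[int, int, int] = (38, 45, 42)
    duration: float = 600.0
    noise_sd: float = 2.0
    jitter_sd: float = 0.9
    window_lengths: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
    analysis_window: float = 12.0
    p_rank: int = 100
    k_rank: int = 5
    p_eval: int = 5
    k_eval: int = 5
    candidate_stride: int = 1
    candidate_sizes: tuple[int, ...] | None = None
    n_trials: int = DEFAULT_N_TRIALS
    n_estimators: int = DEFAULT_N_ESTIMATORS
    n_oof_folds: int = 5
    run_window_sweep: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("n_subjects", "window_lengths", "candidate_sizes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _stage_manifest_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f"manifest_{stage}.json"


def _stage_cached(out_dir: Path, stage: str, cfg: RunConfig) -> bool:
    p = _stage_manifest_path(out_dir, stage)
    if not p.exists():
        return False
    manifest = json.loads(p.read_text())
    if manifest.get("config_hash") != cfg.config_hash():
        return False
    return all((out_dir / f).exists() for f in manifest.get("outputs", []))


def _write_manifest(out_dir: Path, stage: str, cfg: RunConfig,
                    outputs: Sequence[str]) -> None:
    payload = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "outputs": list(outputs),
    }
    _stage_manifest_path(out_dir, stage).write_text(json.dumps(payload, indent=2))


def run(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(cfg.to_json())

    stage_simulate(cfg)
    stage_features(cfg)
    stage_tune(cfg)
    stage_select(cfg)
    stage_evaluate(cfg)
    stage_report(cfg)
    return out_dir


def _run_stage(stage: str, cfg: RunConfig, fn, outputs: Sequence[str]) -> None:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if _stage_cached(out_dir, stage, cfg):
        log.info("stage %s: cached, skipping", stage)
        return
    log.info("stage %s: running (seed=%d)", stage, cfg.seed)
    try:
        fn(out_dir)
    except FileNotFoundError:
        raise  # missing inputs are a data error, not a stage failure
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        raise StageError(stage, exc) from exc
    _write_manifest(out_dir, stage, cfg, outputs)


def stage_simulate(cfg: RunConfig) -> None:
    def _do(out_dir: Path) -> None:
        if cfg.edf_dir is not None:
            log.info("using existing EDF directory %s", cfg.edf_dir)
            return
        templates = default_templates(
            n_subjects=cfg.n_subjects, duration=cfg.duration,
            noise_sd=cfg.noise_sd, jitter_sd=cfg.jitter_sd)
        recordings = generate_cohort(templates, seed=cfg.seed)
        write_cohort(recordings, out_dir / "edf")
        (out_dir / "templates.json").write_text(json.dumps(
            [json.loads(t.to_json()) for t in templates], indent=2))

    outputs = [] if cfg.edf_dir is not None else ["edf/labels.tsv",
                                                  "templates.json"]
    _run_stage("simulate", cfg, _do, outputs)


def _load_recordings(cfg: RunConfig):
    edf_dir = Path(cfg.edf_dir) if cfg.edf_dir else Path(cfg.out_dir) / "edf"
    return read_cohort(edf_dir)


def stage_features(cfg: RunConfig) -> None:
    lengths = sorted(set(cfg.window_lengths) | {cfg.analysis_window})

    def _do(out_dir: Path) -> None:
        recordings = _load_recordings(cfg)
        for wl in lengths:
            df = cohort_features(recordings, wl)
            df.to_csv(out_dir / f"features_w{wl:g}.tsv", sep="\t", index=False)

    _run_stage("features", cfg, _do,
               [f"features_w{wl:g}.tsv" for wl in lengths])


def _load_features(cfg: RunConfig, window_length: float) -> pd.DataFrame:
    path = Path(cfg.out_dir) / f"features_w{window_length:g}.tsv"
    return pd.read_csv(path, sep="\t")


def stage_tune(cfg: RunConfig) -> None:
    def _do(out_dir: Path) -> None:
        df = _load_features(cfg, cfg.analysis_window)
        X, y, _ = split_feature_table(df)
        tuned = {}
        logs = {}
        for name in MODEL_NAMES:
            best, trials = tune(name, X, y, n_trials=cfg.n_trials,
                                seed=cfg.seed, n_estimators=cfg.n_estimators)
            tuned[name] = best
            logs[name] = trials
        (out_dir / "tuned_params.json").write_text(json.dumps(tuned, indent=2))
        (out_dir / "tuning_trials.json").write_text(json.dumps(logs, indent=2))

    _run_stage("tune", cfg, _do, ["tuned_params.json", "tuning_trials.json"])


def _load_params(cfg: RunConfig) -> dict:
    return json.loads((Path(cfg.out_dir) / "tuned_params.json").read_text())


def stage_select(cfg: RunConfig) -> None:
    def _do(out_dir: Path) -> None:
        df = _load_features(cfg, cfg.analysis_window)
        X, y, _ = split_feature_table(df)
        index = build_full_index(X, y, p=cfg.p_rank, k=cfg.k_rank,
                                 seed=cfg.seed, n_estimators=cfg.n_estimators)
        np.savetxt(out_dir / "importance_index.tsv", index.rows, fmt="%d",
                   delimiter="\t")
        (out_dir / "importance_index_meta.json").write_text(json.dumps(
            {"provenance": index.provenance,
             "d_feature": index.d_feature}, indent=2))
        params = _load_params(cfg)
        candidates = cfg.candidate_sizes
        best, sweep = select_optimal_subset(
            index, X, y, candidate_sizes=candidates,
            params_per_model=params, p_eval=cfg.p_eval, k_eval=cfg.k_eval,
            seed=cfg.seed, n_estimators=cfg.n_estimators,
            n_oof_folds=cfg.n_oof_folds, stride=cfg.candidate_stride)
        sweep.to_csv(out_dir / "subset_sweep.tsv", sep="\t", index=False)
        (out_dir / "optimal_subset.json").write_text(json.dumps({
            "n": best.n,
            "features": [int(f) for f in best.features],
            "metrics_mean": best.metrics_mean,
            "metrics_sd": best.metrics_sd,
        }, indent=2))

    _run_stage("select", cfg, _do,
               ["importance_index.tsv", "importance_index_meta.json",
                "subset_sweep.tsv", "optimal_subset.json"])


def stage_evaluate(cfg: RunConfig) -> None:
    outputs = ["rhythm_results.tsv", "model_comparison.tsv"]
    if cfg.run_window_sweep:
        outputs.append("window_sweep.tsv")

    def _do(out_dir: Path) -> None:
        params = _load_params(cfg)
        subset = json.loads((out_dir / "optimal_subset.json").read_text())
        df = _load_features(cfg, cfg.analysis_window)
        if cfg.run_window_sweep:
            recordings = _load_recordings(cfg)
            sweep = window_sweep(
                recordings, cfg.window_lengths, params, cfg.p_eval,
                cfg.k_eval, cfg.seed, cfg.n_estimators, cfg.n_oof_folds)
            sweep.to_csv(out_dir / "window_sweep.tsv", sep="\t", index=False)
        rhythm_df, samples = rhythm_experiments(
            subset["features"], df, params, cfg.p_eval, cfg.k_eval,
            cfg.seed, cfg.n_estimators, cfg.n_oof_folds)
        rhythm_df.to_csv(out_dir / "rhythm_results.tsv", sep="\t", index=False)
        comp_rows = []
        for rhythm, model_samples in samples.items():
            acc = {m: model_samples[m]["accuracy"] for m in model_samples}
            comp = compare_models(acc, reference="ensemble")
            for _, row in comp.pairwise.iterrows():
                comp_rows.append({
                    "rhythm": rhythm, "model": row["model"],
                    "reference": row["reference"],
                    "omnibus_p": comp.omnibus_p,
                    "omnibus_tier": comp.omnibus_tier,
                    "p_adj": row["p_adj"], "tier": row["tier"],
                })
        pd.DataFrame(comp_rows).to_csv(out_dir / "model_comparison.tsv",
                                       sep="\t", index=False)

    _run_stage("evaluate", cfg, _do, outputs)


def stage_report(cfg: RunConfig) -> None:
    def _do(out_dir: Path) -> None:
        subset = json.loads((out_dir / "optimal_subset.json").read_text())
        ids = subset["features"]
        df = _load_features(cfg, cfg.analysis_window)
        counts = count_per_rhythm(ids)
        (out_dir / "rhythm_counts.json").write_text(json.dumps(counts, indent=2))
        region_strength(ids, df).to_csv(out_dir / "region_strength.tsv",
                                        sep="\t", index=False)
        edge_list(ids, df).to_csv(out_dir / "key_edges.tsv", sep="\t",
                                  index=False)

    _run_stage("report", cfg, _do,
               ["rhythm_counts.json", "region_strength.tsv", "key_edges.tsv"])
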