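"""Pipeline orchestration: simulate -> blocks -> spectra -> analyses.

Each stage writes plain inspectable artifacts (CSV/JSON) into the run
directory so stages can be rerun and audited independently; a manifest
lists every artifact a run produced, with the configuration and seeds
that produced it.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthdata import ScenarioConfig, TASK_FAMILIES

log = logging.getLogger(__name__)

STAGES = ("simulate", "blocks", "spectra", "cohort", "envelope", "score", "vae")
_DEPENDS = {
    "simulate": None,
    "blocks": "simulate",
    "spectra": "simulate",
    "cohort": "spectra",
    "envelope": "spectra",
    "score": None,  # generates its own task sessions
    "vae": None,  # generates its own windowed dataset
}


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifacts."""


@dataclass
class PipelineConfig:
    """Configuration of a full run; round-trips losslessly through JSON."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    out_dir: str = "results/pipeline"
    n_bins: int = 11
    f_min: float = 0.25
    f_max: float = 25.0
    gap_tol: float = 1.0
    drift_tol: float = 0.01
    envelope_k: int = 5
    lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    score_subjects: int = 12
    score_boot: int = 200
    vae_subjects: int = 12
    vae_windows_per_task: int = 45
    vae_epochs: int = 30
    vae_lr: float = 1e-3
    vae_batch: int = 128
    seeds: dict = field(default_factory=lambda: {"sessions": 1, "score": 2, "vae": 3})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["symptom_rates"] = dict(self.scenario.symptom_rates)
        d["scenario"]["activity_mix"] = dict(self.scenario.activity_mix)
        d["scenario"]["baseline_severity"] = {
            k: list(v) for k, v in self.scenario.baseline_severity.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scen = dict(d["scenario"])
        scen["baseline_severity"] = {k: tuple(v)
                                     for k, v in scen["baseline_severity"].items()}
        d["scenario"] = ScenarioConfig(**scen)
        d["lambda_grid"] = tuple(d["lambda_grid"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


def proportion_summary(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


class _Run:
    """Bookkeeping for one pipeline invocation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[str] = []
        self.cache: dict = {}

    def path(self, name: str) -> Path:
        p = self.out / name
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def write_json(self, name: str, obj) -> None:
        self.path(name).write_text(json.dumps(obj, indent=2, default=float))
        self.artifacts.append(name)

    def write_csv(self, name: str, df: pd.DataFrame) -> None:
        df.to_csv(self.path(name), index=False, float_format="%.4f")
        self.artifacts.append(name)


def _binning(config: PipelineConfig):
    from .spectra import log_bin_edges

    return log_bin_edges(config.n_bins, config.f_min, config.f_max)


def _require(run: _Run, stage: str, name: str):
    """Fetch an upstream product from this run or fail with the stage name."""
    if name not in run.cache:
        dep = _DEPENDS[stage]
        raise DependencyError(
            f"stage '{stage}' requires artifacts from stage '{dep}'; "
            f"run it first (missing: {name})")
    return run.cache[name]


def _stage_simulate(run: _Run) -> None:
    from .synthdata import diary_frame, generate_scenario, truth_dict

    recordings, diary, truth = generate_scenario(run.config.scenario)
    run.cache["recordings"] = recordings
    run.cache["diary"] = diary
    run.write_csv("diary.csv", diary_frame(diary))
    run.write_json("truth.json", truth_dict(truth))
    run.write_json("scenario_summary.json", {
        "n_patients": run.config.scenario.n_patients,
        "n_controls": run.config.scenario.n_controls,
        "n_true_events": len(truth.true_events),
        "n_diary_events": len(diary),
        "samples_per_subject": [r.n_samples for r in recordings],
    })


def _stage_blocks(run: _Run) -> None:
    from .blocks import acceptance_report, segment_blocks, validate_block

    recordings = _require(run, "blocks", "recordings")
    rows, validated = [], []
    for rec in recordings:
        for blk in segment_blocks(rec):
            blk = validate_block(blk, run.config.gap_tol, run.config.drift_tol)
            validated.append(blk)
            rows.append({"subject": blk.subject_id, "start_index": blk.start_index,
                         "start_time": blk.start_time, "valid": blk.valid,
                         "reject_reason": blk.reject_reason or ""})
    run.cache["blocks"] = validated
    run.write_csv("blocks.csv", pd.DataFrame(rows))
    run.write_json("block_acceptance.json", acceptance_report(validated))


def _stage_spectra(run: _Run) -> None:
    from .spectra import spectral_feature_table

    recordings = _require(run, "spectra", "recordings")
    features = spectral_feature_table(recordings, _binning(run.config),
                                      channel_sets=("device", "g"),
                                      gap_tol=run.config.gap_tol,
                                      drift_tol=run.config.drift_tol)
    run.cache["features"] = features
    run.write_csv("features.csv", features)


def _stage_cohort(run: _Run) -> None:
    from .cohort import cohort_zscores, loo_roc, subject_mean_spectrum
    from .spectra import bin_columns

    features = _require(run, "cohort", "features")
    z = cohort_zscores(features)
    run.write_csv("zscores.csv", z)
    means = subject_mean_spectrum(features, "x")
    roc = loo_roc(means[bin_columns(means)], means["cohort"],
                  subjects=means["subject"].to_numpy())
    run.write_json("roc.json", {
        "auc": roc.auc,
        "subjects": roc.subjects.tolist(),
        "scores": roc.scores.tolist(),
        "labels": roc.labels.tolist(),
        "fpr": roc.fpr.tolist(),
        "tpr": roc.tpr.tolist(),
    })


def _stage_envelope(run: _Run) -> None:
    from .blocks import HOP
    from .envelopes import (build_event_tensor, envelope_summary,
                            fit_rank1_envelope, select_events)
    from .spectra import spectral_block
    from .blocks import segment_blocks, validate_block

    features = _require(run, "envelope", "features")  # ensures spectra ran
    recordings = run.cache["recordings"]
    diary = run.cache["diary"]
    binning = _binning(run.config)
    sblocks = []
    for rec in recordings:
        for blk in segment_blocks(rec):
            blk = validate_block(blk, run.config.gap_tol, run.config.drift_tol)
            if blk.valid:
                sblocks.append(spectral_block(blk, binning, "device"))
    events = select_events(diary)
    hop_s = HOP / run.config.scenario.sampling_rate
    out = {}
    for group in ("tremor", "other"):
        sel = [e for e in events if e.symptom_class == group]
        if not sel:
            out[group] = {"n_events": 0, "note": "no events"}
            continue
        try:
            tensor = build_event_tensor(sel, sblocks, K=run.config.envelope_k,
                                        hop_seconds=hop_s)
        except ValueError as exc:
            out[group] = {"n_events": 0, "note": str(exc)}
            continue
        fit = fit_rank1_envelope(tensor)
        out[group] = envelope_summary(fit, tensor)
    run.write_json("envelopes.json", out)


def _stage_score(run: _Run) -> None:
    from .scoring import (SYMPTOM_POLARITY, accelerometer_scores,
                          estimate_task_drug_effects, fit_ordinal_scorer,
                          spectral_feature_matrix)
    from .synthdata import generate_task_sessions

    cfg = run.config
    sessions, signals, _ = generate_task_sessions(
        n_subjects=cfg.score_subjects, config=cfg.scenario,
        seed=cfg.seeds.get("sessions", 1))
    dominant = sessions["wear_hand"] == "right"
    sessions = sessions[dominant].reset_index(drop=True)
    signals = [s for s, keep in zip(signals, dominant) if keep]
    features = spectral_feature_matrix(signals, cfg.scenario.sampling_rate,
                                       _binning(cfg))
    run.write_csv("sessions.csv", sessions)
    effects_out = {}
    scored = sessions[["subject", "visit", "session", "session_id", "task",
                       "drug_state"]].copy()
    for symptom in SYMPTOM_POLARITY:
        model = fit_ordinal_scorer(features, sessions[f"{symptom}_score"],
                                   groups=sessions["subject"],
                                   lambda_grid=cfg.lambda_grid,
                                   seed=cfg.seeds.get("score", 2))
        scored[f"{symptom}_accel_score"] = accelerometer_scores(model, features)
        df = scored.rename(columns={f"{symptom}_accel_score": "score"})
        eff = estimate_task_drug_effects(
            df[["subject", "session_id", "task", "drug_state", "score"]],
            n_boot=cfg.score_boot, seed=cfg.seeds.get("score", 2))
        effects_out[symptom] = eff.to_dict(orient="records")
    run.write_csv("accelerometer_scores.csv", scored)
    run.write_json("task_effects.json", effects_out)


def _stage_vae(run: _Run) -> None:
    from .synthdata import generate_windowed_task_dataset
    from .vae import (encode_latent, evaluate_task_classification,
                      evaluate_transfer, family_confusion_contrast, train_vae)

    cfg = run.config
    seed = cfg.seeds.get("vae", 3)
    X, y, g = generate_windowed_task_dataset(
        n_subjects=cfg.vae_subjects, windows_per_task=cfg.vae_windows_per_task,
        config=cfg.scenario, seed=seed)
    model = train_vae(X, epochs=cfg.vae_epochs, lr=cfg.vae_lr,
                      batch=cfg.vae_batch, seed=seed)
    mu, _ = encode_latent(model, X)
    result = evaluate_task_classification(mu, y, g, seed=seed)
    same, cross = family_confusion_contrast(result.confusion, TASK_FAMILIES)

    # transfer: fresh cohort, encoded with the trained VAE
    Xb, yb, _ = generate_windowed_task_dataset(
        n_subjects=max(4, cfg.vae_subjects // 2),
        windows_per_task=max(5, cfg.vae_windows_per_task // 3),
        config=cfg.scenario, seed=seed + 1)
    mub, _ = encode_latent(model, Xb)
    transfer = evaluate_transfer(mu, y, mub, yb, seed=seed)

    run.write_csv("vae_confusion.csv", result.confusion.reset_index())
    run.write_json("vae_eval.json", {
        "within_accuracy": result.accuracy,
        "fold_accuracies": result.fold_accuracies,
        "chance": result.chance,
        "same_family_confusion": same,
        "cross_family_confusion": cross,
        "transfer_accuracy": transfer.accuracy,
        "final_elbo": model.final_elbo,
        "n_windows": int(X.shape[0]),
    })


_STAGE_FN = {
    "simulate": _stage_simulate,
    "blocks": _stage_blocks,
    "spectra": _stage_spectra,
    "cohort": _stage_cohort,
    "envelope": _stage_envelope,
    "score": _stage_score,
    "vae": _stage_vae,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order and return the run manifest.

    Stages are idempotent given (config, seeds).  A stage whose upstream
    products are absent raises :class:`DependencyError` naming the missing
    stage.
    """
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(config)
    started = time.time()
    for stage in chosen:
        log.info("stage=%s seed=%s", stage, config.scenario.seed)
        _STAGE_FN[stage](run)
    manifest = {
        "stages": chosen,
        "config": config.to_dict(),
        "seeds": {"scenario": config.scenario.seed, **config.seeds},
        "artifacts": sorted(run.artifacts),
        "versions": {"wristpd": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "started": started,
        "finished": time.time(),
    }
    run.path("manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
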