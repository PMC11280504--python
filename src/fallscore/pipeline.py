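"""End-to-end orchestration: cohort → angles → repetitions → model → scores.

One call (or the ``fallscore demo`` subcommand) runs the whole chain on a
synthetic cohort and writes every artefact — scores, ROC sweep, metrics,
model checkpoint and the resolved configuration — into a run directory.
Everything is driven by a single seed, so a rerun with the same
configuration reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autoencoder, scoring, segmentation, skeleton_io, synthetic_data
from .kinematics import compute_angle_series

__all__ = ["PipelineConfig", "PipelineResult", "run_end_to_end"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one end-to-end run."""

    cohort: synthetic_data.CohortSpec = field(
        default_factory=synthetic_data.CohortSpec)
    segmentation: segmentation.SegmentationConfig = field(
        default_factory=segmentation.SegmentationConfig)
    model: autoencoder.ModelConfig = field(default_factory=autoencoder.ModelConfig)
    clip_frames: int = 30
    sigma_mode: str = "variance"
    val_fraction: float = 0.2      # healthy subjects held out for early stopping
    threshold: float | None = None  # None → select from the ROC of the test scores
    seed: int = 0

    def resolve_seeds(self) -> "PipelineConfig":
        """Derive cohort and model seeds from the run seed."""
        ss = np.random.SeedSequence(self.seed)
        cohort_seed, model_seed = (int(s.generate_state(1)[0] % 2**31)
                                   for s in ss.spawn(2))
        cfg = dataclasses.replace(self)
        cfg.cohort = dataclasses.replace(self.cohort, seed=cohort_seed)
        cfg.model = dataclasses.replace(self.model, seed=model_seed)
        return cfg


@dataclass
class PipelineResult:
    """In-memory summary of a finished run."""

    run_dir: Path
    trained: autoencoder.TrainedModel
    scored: list[scoring.ScoredSubject]
    threshold: float
    auc: float
    metrics: dict


def _segment_cohort(
    recordings: list[skeleton_io.SkeletonRecording],
    seg_cfg: segmentation.SegmentationConfig,
) -> dict[str, list[skeleton_io.Repetition]]:
    cohort: dict[str, list[skeleton_io.Repetition]] = {}
    for rec in recordings:
        series = compute_angle_series(rec)
        reps = segmentation.extract_repetitions(
            series, seg_cfg, subject_id=rec.subject_id,
            class_label=rec.class_label)
        if reps:
            cohort[rec.subject_id] = reps
        else:
            log.warning("subject %s yielded no valid repetitions", rec.subject_id)
    return cohort


def run_end_to_end(config: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    """Run synth → angles → segment → train → score → evaluate and write
    scores.csv, roc.csv, metrics.json, the model checkpoint and a config
    echo into ``run_dir``."""
    cfg = config.resolve_seeds()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    recordings = synthetic_data.generate_cohort(cfg.cohort)
    cohort = _segment_cohort(recordings, cfg.segmentation)

    healthy_train = sorted(
        s for s, reps in cohort.items() if reps[0].class_label == "HealthyAdult")
    test_subjects = sorted(s for s in cohort if s not in set(healthy_train))
    if not healthy_train:
        raise RuntimeError("no healthy training subjects survived segmentation")

    n_val = max(1, int(round(cfg.val_fraction * len(healthy_train))))
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(healthy_train))
    val_ids, train_ids = set(order[:n_val]), order[n_val:]
    train_reps = [r for s in train_ids for r in cohort[s]]
    val_reps = [r for s in sorted(val_ids) for r in cohort[s]]

    trained = autoencoder.train(
        autoencoder.build_model(cfg.model), train_reps, val_reps, cfg.model)
    autoencoder.save_model(trained, run_dir / "model")

    scored = [
        scoring.score_subject(trained, cohort[s], cfg.clip_frames, cfg.sigma_mode)
        for s in test_subjects
    ]
    threshold, roc_points, auc = scoring.roc_threshold(scored)
    if cfg.threshold is not None:
        threshold = cfg.threshold
    for s in scored:
        s.verdict = scoring.classify(s, threshold)

    truths = np.array([s.binary_truth == "AtRisk" for s in scored])
    scores = np.array([s.score for s in scored])
    tp, fn, fp, tn = scoring.confusion_counts(scores, truths, threshold)
    metrics = {
        "auc": auc,
        "threshold": threshold,
        **scoring.confusion_metrics(tp, fn, fp, tn),
        "n_test_subjects": len(scored),
        "n_train_subjects": len(train_ids),
        "n_val_subjects": len(val_ids),
        "stopped_epoch": trained.stopped_epoch,
    }

    pd.DataFrame([{
        "subject_id": s.subject_id,
        "class_label": s.class_label,
        "n_reps": s.n_reps,
        "mean_ed": s.mean_ed,
        "sigma_ed": s.sigma_ed,
        "score": s.score,
        "verdict": s.verdict,
    } for s in scored]).to_csv(run_dir / "scores.csv", index=False,
                               float_format="%.12g")
    pd.DataFrame(roc_points, columns=["fpr", "tpr", "threshold"]).to_csv(
        run_dir / "roc.csv", index=False, float_format="%.12g")
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (run_dir / "config.json").write_text(json.dumps(
        dataclasses.asdict(cfg), indent=2, default=str))

    return PipelineResult(
        run_dir=run_dir, trained=trained, scored=scored,
        threshold=threshold, auc=auc, metrics=metrics,
    )
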