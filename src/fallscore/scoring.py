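"""Falls-risk scoring, threshold selection and evaluation.

A recording's repetitions each get a reconstruction error ED_i from the
healthy-trained autoencoder.  The falls-risk score combines the size of
those errors with their spread across repetitions:

    score = (1/n) * sum_i [ 1 - ED_i * sigma_ED ]  =  1 - sigma_ED * mean(ED)

where sigma_ED is the variance of the ED_i within the recording.  Healthy
movers produce small, consistent errors (score near 1); at-risk movers
produce larger and — crucially — more variable errors, which drags the score
down.  The score is bounded above by 1, may go negative for extreme inputs,
and lower means higher risk.

An at-risk decision threshold is read off a ROC curve built by sweeping the
observed score range; the threshold maximising Youden's J (TPR - FPR) is
chosen, with ties broken toward the higher threshold (favouring
sensitivity).  A subject is called AtRisk when score < threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autoencoder import (
    LSTMAutoencoder,
    ModelConfig,
    TrainedModel,
    build_model,
    reconstruct,
    reconstruction_error,
    train,
)
from .skeleton_io import AT_RISK_LABELS, NOT_AT_RISK_LABELS, Repetition

__all__ = [
    "RepErrorSet",
    "ScoredSubject",
    "binary_truth",
    "falls_risk_score",
    "score_subject",
    "roc_threshold",
    "classify",
    "confusion_counts",
    "confusion_metrics",
    "crossval_metrics",
    "CrossValResult",
]

log = logging.getLogger(__name__)


@dataclass
class RepErrorSet:
    """Per-repetition reconstruction errors for one recording.

    ``sigma_ed`` is the population variance of the errors by default
    (``sigma_mode='variance'``); standard deviation is available as an
    option (``sigma_mode='std'``).
    """

    subject_id: str
    eds: list[float]
    sigma_mode: str = "variance"

    def __post_init__(self) -> None:
        self.eds = [float(e) for e in self.eds]
        if len(self.eds) == 0:
            raise ValueError("RepErrorSet needs at least one repetition")
        if any(e < 0 for e in self.eds):
            raise ValueError("reconstruction errors must be nonnegative")
        if self.sigma_mode not in ("variance", "std"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")

    @property
    def n(self) -> int:
        return len(self.eds)

    @property
    def sigma_ed(self) -> float:
        var = float(np.var(self.eds))  # population variance (ddof=0)
        return var if self.sigma_mode == "variance" else float(np.sqrt(var))


@dataclass
class ScoredSubject:
    """One evaluated subject: continuous score plus binary ground truth."""

    subject_id: str
    class_label: str
    score: float
    n_reps: int = 0
    mean_ed: float = 0.0
    sigma_ed: float = 0.0
    verdict: str | None = None

    @property
    def binary_truth(self) -> str:
        return binary_truth(self.class_label)


def binary_truth(class_label: str) -> str:
    """Map a cohort class label onto the binary falls-risk ground truth."""
    if class_label in AT_RISK_LABELS:
        return "AtRisk"
    if class_label in NOT_AT_RISK_LABELS:
        return "NotAtRisk"
    raise ValueError(
        f"class {class_label!r} has no binary falls-risk label "
        "(HealthyAdult is the training class, not an evaluation class)"
    )


def falls_risk_score(errs: RepErrorSet) -> float:
    """Continuous falls-risk score: mean over repetitions of 1 - ED_i*sigma_ED.

    Algebraically equal to 1 - sigma_ED * mean(ED).  Always <= 1; equals 1
    exactly when the errors are all equal (zero spread) or all zero.  Not
    clamped below: extreme error/spread products can push it negative.
    """
    eds = np.asarray(errs.eds)
    return float(np.mean(1.0 - eds * errs.sigma_ed))


def score_subject(
    model: TrainedModel | LSTMAutoencoder,
    reps: Sequence[Repetition],
    clip_frames: int = 30,
    sigma_mode: str = "variance",
) -> ScoredSubject:
    """Score one subject's recording: reconstruct each repetition, take the
    clipped Euclidean reconstruction errors, and apply the risk score."""
    if len(reps) == 0:
        raise ValueError("no repetitions to score")
    subjects = {r.subject_id for r in reps}
    if len(subjects) != 1:
        raise ValueError(f"repetitions span multiple subjects: {sorted(subjects)}")
    labels = {r.class_label for r in reps}
    if len(labels) != 1:
        raise ValueError(f"inconsistent class labels: {sorted(labels)}")
    eds = [
        reconstruction_error(rep, reconstruct(model, rep), clip_frames)
        for rep in reps
    ]
    errs = RepErrorSet(subject_id=reps[0].subject_id, eds=eds, sigma_mode=sigma_mode)
    if errs.n == 1:
        log.warning(
            "subject %s has a single repetition; sigma_ED is 0 and the "
            "score degenerates to exactly 1", errs.subject_id,
        )
    return ScoredSubject(
        subject_id=errs.subject_id,
        class_label=reps[0].class_label,
        score=falls_risk_score(errs),
        n_reps=errs.n,
        mean_ed=float(np.mean(errs.eds)),
        sigma_ed=errs.sigma_ed,
    )


# ---------------------------------------------------------------------------
# ROC threshold selection and classification
# ---------------------------------------------------------------------------

def confusion_counts(scores, truths, threshold):
    """(TP, FN, FP, TN) counts with AtRisk predicted when score < threshold.

    ``truths`` is a boolean array, True for the AtRisk class.
    """
    pred_risk = scores < threshold
    true_risk = truths
    tp = int(np.sum(pred_risk & true_risk))
    fn = int(np.sum(~pred_risk & true_risk))
    fp = int(np.sum(pred_risk & ~true_risk))
    tn = int(np.sum(~pred_risk & ~true_risk))
    return tp, fn, fp, tn


def roc_threshold(
    scored: Sequence[ScoredSubject],
    grid: Sequence[float] | None = None,
) -> tuple[float, np.ndarray, float]:
    """Sweep score thresholds and pick the best operating point.

    AtRisk is predicted when score < threshold.  The default grid is the
    unique observed scores plus their midpoints, extended just past the
    maximum so both trivial classifiers appear on the curve.  Returns
    ``(threshold, roc_points, auc)`` where ``roc_points`` is an array of
    (fpr, tpr, threshold) rows sorted along the curve and ``auc`` is the
    trapezoidal area (identical to the rank-based Mann-Whitney AUC).

    The chosen threshold maximises Youden's J = TPR - FPR; ties break toward
    the higher threshold.
    """
    scores = np.array([s.score for s in scored], dtype=float)
    truths = np.array([s.binary_truth == "AtRisk" for s in scored])
    if truths.all() or not truths.any():
        raise ValueError("both classes must be present to build a ROC")
    if grid is None:
        uniq = np.unique(scores)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        span = uniq[-1] - uniq[0] if uniq.size > 1 else 1.0
        grid = np.concatenate((uniq, mids, [uniq[-1] + 0.01 * span + 1e-12]))
    grid = np.sort(np.asarray(grid, dtype=float))

    n_pos = int(truths.sum())
    n_neg = truths.size - n_pos
    rows = []
    for thr in grid:
        tp, fn, fp, tn = confusion_counts(scores, truths, thr)
        rows.append((fp / n_neg, tp / n_pos, thr))
    points = np.array(rows)
    # close the curve at (0,0) and (1,1) for the area computation
    fprs = np.concatenate(([0.0], points[:, 0], [1.0]))
    tprs = np.concatenate(([0.0], points[:, 1], [1.0]))
    order = np.lexsort((tprs, fprs))
    auc = float(np.trapezoid(tprs[order], fprs[order]))

    youden = points[:, 1] - points[:, 0]
    best_j = youden.max()
    best_thr = float(points[np.isclose(youden, best_j), 2].max())
    return best_thr, points, auc


def classify(scored: ScoredSubject, threshold: float) -> str:
    """AtRisk iff score < threshold; a score equal to the threshold is
    NotAtRisk."""
    return "AtRisk" if scored.score < threshold else "NotAtRisk"


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Per-fold and summary classification metrics."""

    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    std: dict[str, float]
    ci95: dict[str, float]
    threshold: float


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    total = tp + fn + fp + tn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
    }


def crossval_metrics(
    cohort: Mapping[str, Sequence[Repetition]],
    k: int = 5,
    seed: int = 0,
    threshold: float | None = None,
    model_config: ModelConfig | None = None,
    clip_frames: int = 30,
    sigma_mode: str = "variance",
    val_fraction: float = 0.2,
) -> CrossValResult:
    """Subject-level k-fold evaluation with per-fold retraining.

    ``cohort`` maps subject_id → that subject's repetitions (any class).
    HealthyAdult subjects are the training pool; the other classes carry the
    binary ground truth and are the evaluation pool.  Both pools are split
    into k folds (the evaluation pool stratified by binary class); fold i
    trains the autoencoder on healthy subjects outside fold i (a fraction
    held out for validation/early stopping) and scores the evaluation
    subjects inside fold i.  No subject appears in both train and test.

    If ``threshold`` is None it is selected per fold by a ROC on that fold's
    *training-side* evaluation subjects (out-of-fold selection); passing a
    fixed threshold mirrors reusing one chosen in advance.
    """
    rng = np.random.default_rng(seed)
    healthy = sorted(s for s, reps in cohort.items()
                     if reps[0].class_label == "HealthyAdult")
    eval_subjects = sorted(s for s in cohort if s not in set(healthy))
    if not healthy:
        raise ValueError("no HealthyAdult subjects to train on")

    # stratified fold assignment for evaluation subjects
    fold_of: dict[str, int] = {}
    for cls in ("AtRisk", "NotAtRisk"):
        members = [s for s in eval_subjects
                   if binary_truth(cohort[s][0].class_label) == cls]
        members = list(rng.permutation(members))
        if len(members) < k:
            raise ValueError(
                f"cannot stratify: only {len(members)} {cls} subjects for {k} folds"
            )
        for i, s in enumerate(members):
            fold_of[s] = i % k
    healthy_perm = list(rng.permutation(healthy))
    healthy_fold = {s: i % k for i, s in enumerate(healthy_perm)}

    per_fold: list[dict[str, float]] = []
    thresholds_used: list[float] = []
    for fold in range(k):
        train_healthy = [s for s in healthy if healthy_fold[s] != fold]
        if not train_healthy:
            raise ValueError("a fold has no healthy training subjects")
        n_val = max(1, int(round(val_fraction * len(train_healthy))))
        val_subjects = set(train_healthy[:n_val])
        train_reps = [r for s in train_healthy if s not in val_subjects
                      for r in cohort[s]]
        val_reps = [r for s in val_subjects for r in cohort[s]]
        cfg = model_config or ModelConfig()
        trained = train(build_model(cfg), train_reps, val_reps, cfg)

        test_ids = [s for s in eval_subjects if fold_of[s] == fold]
        scored_test = [
            score_subject(trained, cohort[s], clip_frames, sigma_mode)
            for s in test_ids
        ]
        if threshold is None:
            train_eval_ids = [s for s in eval_subjects if fold_of[s] != fold]
            scored_train = [
                score_subject(trained, cohort[s], clip_frames, sigma_mode)
                for s in train_eval_ids
            ]
            thr, _, _ = roc_threshold(scored_train)
        else:
            thr = threshold
        thresholds_used.append(thr)

        truths = np.array([s.binary_truth == "AtRisk" for s in scored_test])
        if truths.all() or not truths.any():
            raise ValueError(f"fold {fold}: test fold contains a single class")
        scores = np.array([s.score for s in scored_test])
        per_fold.append(confusion_metrics(*confusion_counts(scores, truths, thr)))

    keys = ("accuracy", "specificity", "sensitivity")
    mean = {m: float(np.mean([f[m] for f in per_fold])) for m in keys}
    std = {m: float(np.std([f[m] for f in per_fold], ddof=1)) for m in keys}
    ci95 = {m: 1.96 * std[m] / np.sqrt(k) for m in keys}
    return CrossValResult(
        per_fold=per_fold,
        mean=mean,
        std=std,
        ci95=ci95,
        threshold=float(np.mean(thresholds_used)),
    )
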