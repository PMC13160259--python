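"""Cross-validation drivers and the multilabel metric suite.

Fold plans
----------
``grouped_kfold`` assigns whole patients to folds so that no patient's notes
straddle train and test — the leakage guard needed because a surgeon's
documentation style is patient-correlated.  ``stratified_note_kfold``
assigns notes directly, dealing each class round-robin across folds so
minority classes are represented in every fold they can reach.  Units
listed in ``always_train`` (synthetic augmentation notes) receive fold
``-1``: they join every training split and never appear in a test split.

Metrics
-------
AUC, AUPRC (average-precision step form), micro/macro F1 and Hamming loss,
computed per class and per fold with cross-fold mean and sample SD.  The
macro F1 zero-division convention is conservative: a class with neither
true nor predicted positives contributes F1 = 0.  When a test fold lacks a
class entirely, that class's AUC/AUPRC is skipped for the fold with a
warning rather than imputed.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    hamming_loss as _sk_hamming_loss,
    roc_auc_score,
)

from .cascade import (
    CascadeConfig,
    OvrModel,
    _binary_matrix,
    optimize_threshold,
    train_ovr,
)
from .featurize import TokenStream, fit_tfidf, preprocess, transform_corpus
from .io import OperativeNote
from .taxonomy import DEFAULT_TAXONOMY, LabelTaxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "MetricReport",
    "grouped_kfold",
    "stratified_note_kfold",
    "roc_auc",
    "auprc",
    "f1_scores",
    "hamming_loss",
    "cross_validate",
    "feature_importance",
]

ALWAYS_TRAIN = -1


@dataclass(frozen=True)
class FoldPlan:
    """A fold assignment: unit id -> fold index (-1 = training-only)."""

    level: str
    k: int
    assignments: Mapping[str, int]
    grouping: str  # "patient" | "note"

    def test_units(self, fold: int) -> list:
        return [u for u, f in self.assignments.items() if f == fold]

    def train_units(self, fold: int) -> list:
        return [u for u, f in self.assignments.items() if f != fold]


def grouped_kfold(
    patient_ids: Sequence[str],
    k: int,
    seed: int,
    unit_ids: Optional[Sequence] = None,
    always_train: Sequence = (),
    level: str = "primary",
) -> FoldPlan:
    """Patient-grouped folds: all of a patient's notes share one fold.

    Patients are shuffled by ``seed`` and dealt into ``k`` near-equal
    groups.  Units in ``always_train`` get fold -1; a patient whose units
    are all in ``always_train`` is excluded from the deal.  Errors if fewer
    distinct eligible patients than ``k``.
    """
    n = len(patient_ids)
    if unit_ids is None:
        unit_ids = list(range(n))
    if len(unit_ids) != n:
        raise ValueError("unit_ids and patient_ids must align")
    pinned = set(always_train)
    eligible_patients = sorted({
        p for u, p in zip(unit_ids, patient_ids) if u not in pinned
    })
    if k > len(eligible_patients):
        raise ValueError(
            f"k={k} exceeds the {len(eligible_patients)} distinct eligible patients"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(eligible_patients)))
    shuffled = [eligible_patients[i] for i in order]
    patient_fold = {}
    for group_idx, group in enumerate(np.array_split(shuffled, k)):
        for p in group:
            patient_fold[p] = group_idx
    assignments = {}
    for u, p in zip(unit_ids, patient_ids):
        assignments[u] = ALWAYS_TRAIN if u in pinned else patient_fold[p]
    return FoldPlan(level=level, k=k, assignments=assignments, grouping="patient")


def stratified_note_kfold(
    labels: Sequence,
    k: int,
    seed: int,
    unit_ids: Optional[Sequence] = None,
    always_train: Sequence = (),
    level: str = "subtype",
) -> FoldPlan:
    """Note-level stratified folds via per-class round-robin dealing.

    ``labels`` may be single labels or label sets; a multilabel note is
    dealt with its rarest class.  Classes are processed from rarest to most
    frequent; each class's notes are shuffled by ``seed`` and dealt starting
    at the currently smallest fold.  A class with fewer than ``k`` notes is
    flagged as unstable (it cannot appear in every test fold).
    """
    n = len(labels)
    if unit_ids is None:
        unit_ids = list(range(n))
    pinned = set(always_train)
    norm = [frozenset(l) if isinstance(l, (set, frozenset)) else frozenset({l}) for l in labels]
    counts = Counter(c for lab in norm for c in lab)
    for cls, cnt in sorted(counts.items()):
        if cnt < k:
            logger.warning(
                "class %r has %d note(s) < k=%d folds; per-fold metrics unstable",
                cls, cnt, k,
            )
    rng = np.random.default_rng(seed)
    assignments: dict = {u: ALWAYS_TRAIN for u in unit_ids if u in pinned}
    fold_sizes = [0] * k
    # rarest class first so scarce classes control their own placement
    for cls in sorted(counts, key=lambda c: (counts[c], c)):
        members = [
            i for i in range(n)
            if cls in norm[i] and unit_ids[i] not in assignments
        ]
        if not members:
            continue
        members = [members[i] for i in rng.permutation(len(members))]
        start = int(np.argmin(fold_sizes))
        for offset, i in enumerate(members):
            fold = (start + offset) % k
            assignments[unit_ids[i]] = fold
            fold_sizes[fold] += 1
    for i in range(n):  # label-less notes, if any
        if unit_ids[i] not in assignments:
            fold = int(np.argmin(fold_sizes))
            assignments[unit_ids[i]] = fold
            fold_sizes[fold] += 1
    return FoldPlan(level=level, k=k, assignments=assignments, grouping="note")


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic with tie correction)."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, average-precision step form."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("auprc requires at least one positive label")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def f1_scores(pred, true) -> tuple[float, float, np.ndarray]:
    """(micro F1, macro F1, per-class F1) for binary label matrices.

    Classes with no true and no predicted positives contribute F1 = 0 to the
    macro average.
    """
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same shape")
    if pred.ndim == 2 and pred.shape[1] == 1:
        # single-label-column degenerate case: positive-class F1 everywhere
        # (a lone column would otherwise be read as multiclass labels)
        f1 = float(f1_score(true[:, 0], pred[:, 0], zero_division=0))
        return f1, f1, np.array([f1])
    micro = float(f1_score(true, pred, average="micro", zero_division=0))
    macro = float(f1_score(true, pred, average="macro", zero_division=0))
    per_class = f1_score(true, pred, average=None, zero_division=0)
    return micro, macro, np.asarray(per_class, dtype=float)


def hamming_loss(pred, true) -> float:
    """Fraction of label cells predicted incorrectly."""
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same shape")
    return float(_sk_hamming_loss(true, pred))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class MetricReport:
    """Cross-validated metrics: per fold, per class, and aggregated.

    ``averaged`` maps metric name -> (mean, sd) across folds.  Because the
    order of averaging is ambiguous for macro AUC/AUPRC, both orders are
    emitted: ``macro_auc`` averages the per-fold class-macro (fold mean of
    class means) while ``macro_auc_class_first`` macro-averages the
    per-class cross-fold means.
    """

    level: str
    classes: tuple[str, ...]
    per_fold: list[dict] = field(default_factory=list)
    per_class: dict = field(default_factory=dict)
    averaged: dict = field(default_factory=dict)
    #: class -> ([held-out scores], [labels]) pooled across folds
    pooled_scores: dict = field(default_factory=dict)

    def curve_points(self, kind: str = "roc") -> "pd.DataFrame":
        """ROC ('roc') or precision-recall ('pr') points per class, pooled
        over held-out folds, as a tidy frame for plotting."""
        import pandas as pd
        from sklearn.metrics import precision_recall_curve, roc_curve

        frames = []
        for c, (scores, labels) in self.pooled_scores.items():
            if not labels or len(set(labels)) < 2:
                continue
            if kind == "roc":
                fpr, tpr, thr = roc_curve(labels, scores)
                frames.append(pd.DataFrame(
                    {"class": c, "fpr": fpr, "tpr": tpr,
                     "threshold": np.clip(thr, 0, 1)}))
            elif kind == "pr":
                prec, rec, thr = precision_recall_curve(labels, scores)
                frames.append(pd.DataFrame(
                    {"class": c, "recall": rec, "precision": prec}))
            else:
                raise ValueError("kind must be 'roc' or 'pr'")
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def format_mean_sd(self, metric: str, digits: int = 2) -> str:
        mean, sd = self.averaged[metric]
        return f"{mean:.{digits}f} (SD {sd:.{digits}f})"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "classes": list(self.classes),
            "per_fold": self.per_fold,
            "per_class": self.per_class,
            "averaged": {k: {"mean": m, "sd": s} for k, (m, s) in self.averaged.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "mean", "sd"])
            for metric, (mean, sd) in sorted(self.averaged.items()):
                writer.writerow([metric, f"{mean:.6f}", f"{sd:.6f}"])


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v == v], dtype=float)  # drop NaN
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def cross_validate(
    notes: Sequence[OperativeNote],
    sections: Mapping[str, str],
    plan: FoldPlan,
    classes: Sequence[str],
    config: CascadeConfig = CascadeConfig(),
    level: str = "primary",
    mode: str = "multilabel",
) -> MetricReport:
    """Run the full in-fold pipeline and aggregate metrics across folds.

    Per fold: TF-IDF and the OvR forest are fit on the training split only;
    the held-out split is scored; per-class decision thresholds for F1 and
    Hamming loss are optimized on the held-out scores of that fold (in
    single-label mode predictions are argmax instead).  Synthetic notes
    (fold -1 in the plan) never enter a test split.
    """
    usable = [n for n in notes if n.note_id in sections and n.gold_labels is not None]
    docs = [preprocess(sections[n.note_id], note_id=n.note_id) for n in usable]
    if level == "primary":
        label_sets = [n.gold_labels.primary for n in usable]
    else:
        # conditional levels carry single labels stored per parent class;
        # callers pre-filter notes, here we just read the recorded label
        raise ValueError("use cross_validate_level for conditional levels")
    return _cv(usable, docs, label_sets, plan, classes, config, level, mode)


def cross_validate_level(
    notes: Sequence[OperativeNote],
    sections: Mapping[str, str],
    plan: FoldPlan,
    classes: Sequence[str],
    parent: str,
    which: str,  # "subtype" | "technique"
    config: CascadeConfig = CascadeConfig(),
) -> MetricReport:
    """Cross-validate a conditional (subtype/technique) level in isolation,
    conditioning on gold parent labels exactly as during training."""
    usable, labels = [], []
    for n in notes:
        if n.note_id not in sections or n.gold_labels is None:
            continue
        rec = n.gold_labels
        if parent not in rec.primary:
            continue
        value = (rec.subtype if which == "subtype" else rec.technique).get(parent)
        if value is None:
            continue
        usable.append(n)
        labels.append(frozenset({value}))
    docs = [preprocess(sections[n.note_id], note_id=n.note_id) for n in usable]
    return _cv(usable, docs, labels, plan, classes, config, f"{which}:{parent}", "single")


def _cv(
    usable: Sequence[OperativeNote],
    docs: Sequence[TokenStream],
    label_sets: Sequence[frozenset[str]],
    plan: FoldPlan,
    classes: Sequence[str],
    config: CascadeConfig,
    level: str,
    mode: str,
) -> MetricReport:
    classes = tuple(classes)
    fold_of = np.array([plan.assignments[n.note_id] for n in usable])
    report = MetricReport(level=level, classes=classes)
    per_class_auc: dict[str, list[float]] = {c: [] for c in classes}
    per_class_auprc: dict[str, list[float]] = {c: [] for c in classes}
    per_class_f1: dict[str, list[float]] = {c: [] for c in classes}
    # held-out scores pooled across folds, for ROC/PR curve tables
    report.pooled_scores = {c: ([], []) for c in classes}

    for fold in range(plan.k):
        train_idx = np.where(fold_of != fold)[0]
        test_idx = np.where(fold_of == fold)[0]
        if len(train_idx) == 0 or len(test_idx) == 0:
            logger.warning("%s: fold %d empty; skipped", level, fold)
            continue
        train_labels = [label_sets[i] for i in train_idx]
        missing = [c for c in classes if all(c not in l for l in train_labels)]
        if missing:
            logger.warning("%s: fold %d lacks training class(es) %s; skipped", level, fold, missing)
            continue
        tfidf = fit_tfidf([docs[i] for i in train_idx], config.max_features)
        X_train = transform_corpus([docs[i] for i in train_idx], tfidf)
        X_test = transform_corpus([docs[i] for i in test_idx], tfidf)
        ovr = train_ovr(
            X_train, train_labels, classes,
            seed=config.seed, n_trees=config.n_trees,
            class_weighting=config.class_weighting, mode=mode,
        )
        scores = ovr.score(X_test)
        y_true = _binary_matrix([label_sets[i] for i in test_idx], classes)
        for j, c in enumerate(classes):
            report.pooled_scores[c][0].extend(float(s) for s in scores[c])
            report.pooled_scores[c][1].extend(int(v) for v in y_true[:, j])

        fold_metrics: dict = {"fold": fold, "n_test": int(len(test_idx))}
        aucs, auprcs = [], []
        for j, c in enumerate(classes):
            col = y_true[:, j]
            if col.min() == col.max():
                logger.warning("%s: fold %d test split lacks both outcomes for %r; AUC/AUPRC skipped", level, fold, c)
                continue
            a = roc_auc(scores[c], col)
            p = auprc(scores[c], col)
            per_class_auc[c].append(a)
            per_class_auprc[c].append(p)
            aucs.append(a)
            auprcs.append(p)
        fold_metrics["macro_auc"] = float(np.mean(aucs)) if aucs else float("nan")
        fold_metrics["macro_auprc"] = float(np.mean(auprcs)) if auprcs else float("nan")

        if mode == "single":
            pred_labels = ovr.predict(X_test)
            y_pred = _binary_matrix([frozenset({p}) for p in pred_labels], classes)
            true_labels = [next(iter(label_sets[i])) for i in test_idx]
            fold_metrics["accuracy"] = float(
                np.mean([p == t for p, t in zip(pred_labels, true_labels)])
            )
        else:
            y_pred = np.zeros_like(y_true)
            for j, c in enumerate(classes):
                if y_true[:, j].sum() > 0:
                    t = optimize_threshold(scores[c], y_true[:, j], config.threshold_step)
                else:
                    t = 0.5
                y_pred[:, j] = (np.asarray(scores[c]) >= t).astype(int)
        micro, macro, per_cls = f1_scores(y_pred, y_true)
        for j, c in enumerate(classes):
            per_class_f1[c].append(float(per_cls[j]))
        fold_metrics["micro_f1"] = micro
        fold_metrics["macro_f1"] = macro
        fold_metrics["hamming_loss"] = hamming_loss(y_pred, y_true)
        report.per_fold.append(fold_metrics)

    for c in classes:
        report.per_class[c] = {
            "auc": _mean_sd(per_class_auc[c]),
            "auprc": _mean_sd(per_class_auprc[c]),
            "f1": _mean_sd(per_class_f1[c]),
        }
    metric_names = ["macro_auc", "macro_auprc", "micro_f1", "macro_f1", "hamming_loss"]
    if any("accuracy" in f for f in report.per_fold):
        metric_names.append("accuracy")
    for m in metric_names:
        report.averaged[m] = _mean_sd([f[m] for f in report.per_fold if m in f])
    # alternative averaging order: macro over per-class cross-fold means
    class_means = [report.per_class[c]["auc"][0] for c in classes if per_class_auc[c]]
    report.averaged["macro_auc_class_first"] = (
        (float(np.mean(class_means)), float("nan")) if class_means else (float("nan"), float("nan"))
    )
    return report


# ---------------------------------------------------------------------------
# feature importance


def feature_importance(
    ovr: OvrModel,
    feature_names: Sequence[str],
    top_k: int = 10,
) -> dict[str, list[tuple[str, float]]]:
    """Per-class top-k impurity importances, normalized to max 1 per class.

    Identical (duplicated) feature columns share importance between them and
    therefore rank contiguously.
    """
    report: dict[str, list[tuple[str, float]]] = {}
    for cls in ovr.classes:
        imp = np.asarray(ovr.estimators[cls].feature_importances_, dtype=float)
        order = sorted(range(len(feature_names)), key=lambda i: (-imp[i], feature_names[i]))
        top = order[: min(top_k, len(feature_names))]
        peak = imp[top[0]] if imp[top[0]] > 0 else 1.0
        report[cls] = [(feature_names[i], float(imp[i] / peak)) for i in top]
    return report
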