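"""Three-level One-vs-Rest cascade: procedure type, subtype, technique.

Level 1 (primary) is multilabel: one random-forest scorer per procedure
class, a note receiving every class whose score clears that class's decision
threshold (the empty set is legal).  Levels 2 and 3 are conditional
single-label classifiers trained only on notes whose gold labels contain the
parent class, and applied at inference only when the parent class was
predicted — so primary-level errors propagate downward by design, exactly as
in the isolated-development protocol the cascade mirrors.

Scores are the fraction of trees voting positive, which puts them on [0, 1]
and makes grid thresholds well defined.  Decision thresholds are chosen per
class by maximizing F1 on held-out folds of an internal cross-validation and
averaging across folds; the final scorers are refit on all training data
(or, optionally, the best-performing fold model is kept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .featurize import (
    TfidfModel,
    TokenStream,
    fit_tfidf,
    preprocess,
    transform_corpus,
)
from .io import OperativeNote
from .taxonomy import DEFAULT_TAXONOMY, LabelRecord, LabelTaxonomy

__all__ = [
    "CascadeConfig",
    "OvrModel",
    "CascadeModel",
    "class_weights",
    "train_ovr",
    "optimize_threshold",
    "average_thresholds",
    "predict_primary",
    "train_cascade",
    "classify_cascade",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Training settings for every level of the cascade.

    Defaults: 500 trees, unlimited depth, sqrt(p) features per split,
    balanced class weighting, fixed seed, F1 threshold grid step 0.01,
    patient-grouped 5-fold CV at the primary level and note-level
    stratified 3-fold CV at the conditional levels.
    """

    n_trees: int = 500
    seed: int = 42
    threshold_step: float = 0.01
    max_features: int = 500
    primary_folds: int = 5
    conditional_folds: int = 3
    class_weighting: bool = True
    refit: str = "all"  # "all" | "best_fold"

    def __post_init__(self) -> None:
        if self.refit not in ("all", "best_fold"):
            raise ValueError("refit must be 'all' or 'best_fold'")


def class_weights(label_counts: Mapping[str, int]) -> dict[str, float]:
    """Balanced class weights ``w_c = n_total / (n_classes * n_c)``.

    A zero count is an error: the class is unobserved in the training fold
    and cannot be weighted.
    """
    if any(c <= 0 for c in label_counts.values()):
        missing = sorted(k for k, v in label_counts.items() if v <= 0)
        raise ValueError(f"class(es) with zero training count: {missing}")
    n_total = sum(label_counts.values())
    k = len(label_counts)
    return {cls: n_total / (k * n) for cls, n in label_counts.items()}


@dataclass
class OvrModel:
    """One-vs-Rest ensemble: per-class random-forest scorer + threshold.

    ``mode`` is ``"multilabel"`` (threshold decisions, possibly-empty label
    sets) or ``"single"`` (argmax over class scores).  ``score`` returns the
    fraction of trees voting positive, in [0, 1].
    """

    classes: tuple[str, ...]
    estimators: dict[str, RandomForestClassifier]
    thresholds: dict[str, float] = field(default_factory=dict)
    mode: str = "multilabel"
    seed: int = 42
    n_trees: int = 500

    def score(self, X) -> dict[str, np.ndarray]:
        X = _dense(X)
        out = {}
        for cls in self.classes:
            rf = self.estimators[cls]
            votes = np.mean([tree.predict(X) for tree in rf.estimators_], axis=0)
            out[cls] = votes
        return out

    def predict(self, X) -> list:
        """Label sets (multilabel mode) or single labels (single mode)."""
        scores = self.score(X)
        n = next(iter(scores.values())).shape[0]
        if self.mode == "single":
            mat = np.column_stack([scores[c] for c in self.classes])
            idx = np.argmax(mat, axis=1)  # ties -> first class in order
            return [self.classes[i] for i in idx]
        out = []
        for i in range(n):
            labels = {
                c for c in self.classes if scores[c][i] >= self.thresholds.get(c, 0.5)
            }
            out.append(frozenset(labels))
        return out


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def _binary_matrix(
    labels: Sequence[frozenset[str] | set[str]], classes: Sequence[str]
) -> np.ndarray:
    mat = np.zeros((len(labels), len(classes)), dtype=int)
    for i, lab in enumerate(labels):
        for j, c in enumerate(classes):
            if c in lab:
                mat[i, j] = 1
    return mat


def train_ovr(
    X,
    label_sets: Sequence[frozenset[str] | set[str]],
    classes: Sequence[str],
    seed: int = 42,
    n_trees: int = 500,
    class_weighting: bool = True,
    mode: str = "multilabel",
) -> OvrModel:
    """Train one binary random forest per class (thresholds left unset).

    Each class needs at least one positive and one negative example;
    otherwise a ``ValueError`` naming the class is raised.  Deterministic
    given ``seed``.
    """
    X = _dense(X)
    Y = _binary_matrix(label_sets, classes)
    estimators: dict[str, RandomForestClassifier] = {}
    for j, cls in enumerate(classes):
        y = Y[:, j]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0:
            raise ValueError(f"class {cls!r} has no positive training examples")
        if n_neg == 0:
            raise ValueError(f"class {cls!r} has no negative training examples")
        weight = None
        if class_weighting:
            w = class_weights({"neg": n_neg, "pos": n_pos})
            weight = {0: w["neg"], 1: w["pos"]}
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=None,
            max_features="sqrt",
            class_weight=weight,
            random_state=seed + j,
            n_jobs=1,
        )
        rf.fit(X, y)
        estimators[cls] = rf
    return OvrModel(
        classes=tuple(classes),
        estimators=estimators,
        mode=mode,
        seed=seed,
        n_trees=n_trees,
    )


def optimize_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    step: float = 0.01,
) -> float:
    """Grid threshold maximizing F1 of ``score >= threshold``.

    The grid is {0, step, ..., 1}; ties are broken by the lowest threshold.
    Requires at least one positive label (F1 is undefined otherwise).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("optimize_threshold requires at least one positive label")
    n_grid = int(round(1.0 / step))
    grid = np.linspace(0.0, 1.0, n_grid + 1)
    best_t, best_f1 = 0.0, -1.0
    for t in grid:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1:  # strict: ties keep the earlier (lower) threshold
            best_t, best_f1 = float(t), f1
    return best_t


def average_thresholds(per_fold: Sequence[float]) -> float:
    """Arithmetic mean of per-fold thresholds, clamped to [0, 1]."""
    if not per_fold:
        raise ValueError("average_thresholds requires a non-empty list")
    return float(min(1.0, max(0.0, float(np.mean(per_fold)))))


def predict_primary(model: OvrModel, X) -> tuple[dict[str, np.ndarray], list[frozenset[str]]]:
    """Per-class scores plus thresholded label sets (>= convention)."""
    scores = model.score(X)
    preds = model.predict(X)
    return scores, preds


# ---------------------------------------------------------------------------
# cascade


@dataclass
class LevelModel:
    """A fitted (TF-IDF, OvR) pair for one level or conditional branch."""

    tfidf: TfidfModel
    ovr: OvrModel


@dataclass
class CascadeModel:
    taxonomy: LabelTaxonomy
    config: CascadeConfig
    primary: LevelModel
    subtype_models: dict[str, LevelModel] = field(default_factory=dict)
    technique_models: dict[str, LevelModel] = field(default_factory=dict)
    skipped_levels: list[str] = field(default_factory=list)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "primary_classes": list(self.taxonomy.primary_classes),
            "subtype_classes": {k: list(v) for k, v in self.taxonomy.subtype_classes.items()},
            "technique_classes": {k: list(v) for k, v in self.taxonomy.technique_classes.items()},
            "skipped_levels": self.skipped_levels,
            "thresholds": {
                "primary": self.primary.ovr.thresholds,
                "subtype": {k: m.ovr.thresholds for k, m in self.subtype_models.items()},
                "technique": {k: m.ovr.thresholds for k, m in self.technique_models.items()},
            },
        }
        with open(directory / "cascade.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        self.primary.tfidf.to_json(directory / "tfidf_primary.json")
        joblib.dump(self.primary.ovr, directory / "ovr_primary.joblib")
        for level, models in (("subtype", self.subtype_models), ("technique", self.technique_models)):
            for parent, m in models.items():
                m.tfidf.to_json(directory / f"tfidf_{level}_{parent}.json")
                joblib.dump(m.ovr, directory / f"ovr_{level}_{parent}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        with open(directory / "cascade.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        taxonomy = LabelTaxonomy(
            primary_classes=tuple(meta["primary_classes"]),
            subtype_classes={k: tuple(v) for k, v in meta["subtype_classes"].items()},
            technique_classes={k: tuple(v) for k, v in meta["technique_classes"].items()},
        )
        config = CascadeConfig(**meta["config"])
        primary = LevelModel(
            tfidf=TfidfModel.from_json(directory / "tfidf_primary.json"),
            ovr=joblib.load(directory / "ovr_primary.joblib"),
        )
        model = cls(taxonomy=taxonomy, config=config, primary=primary,
                    skipped_levels=list(meta.get("skipped_levels", [])))
        for level, store in (("subtype", model.subtype_models), ("technique", model.technique_models)):
            for p in directory.glob(f"ovr_{level}_*.joblib"):
                parent = p.stem.replace(f"ovr_{level}_", "")
                store[parent] = LevelModel(
                    tfidf=TfidfModel.from_json(directory / f"tfidf_{level}_{parent}.json"),
                    ovr=joblib.load(p),
                )
        return model


def _tokenize_sections(
    notes: Sequence[OperativeNote], sections: Mapping[str, str]
) -> list[TokenStream]:
    return [preprocess(sections[n.note_id], note_id=n.note_id) for n in notes]


def _fold_thresholds(
    docs: list[TokenStream],
    label_sets: list[frozenset[str]],
    classes: Sequence[str],
    fold_of: np.ndarray,
    k: int,
    config: CascadeConfig,
) -> dict[str, float]:
    """Internal CV: per-class F1-optimal threshold on each held-out fold,
    averaged across the folds where the class has a held-out positive."""
    per_class: dict[str, list[float]] = {c: [] for c in classes}
    for fold in range(k):
        train_idx = [i for i in range(len(docs)) if fold_of[i] != fold]
        test_idx = [i for i in range(len(docs)) if fold_of[i] == fold]
        if not train_idx or not test_idx:
            continue
        train_labels = [label_sets[i] for i in train_idx]
        if any(all(c not in lab for lab in train_labels) for c in classes):
            continue  # a class unobserved in this training fold
        tfidf = fit_tfidf([docs[i] for i in train_idx], config.max_features)
        X_train = transform_corpus([docs[i] for i in train_idx], tfidf)
        X_test = transform_corpus([docs[i] for i in test_idx], tfidf)
        ovr = train_ovr(
            X_train, train_labels, classes,
            seed=config.seed, n_trees=config.n_trees,
            class_weighting=config.class_weighting,
        )
        scores = ovr.score(X_test)
        y_test = _binary_matrix([label_sets[i] for i in test_idx], classes)
        for j, c in enumerate(classes):
            if y_test[:, j].sum() == 0:
                continue
            per_class[c].append(
                optimize_threshold(scores[c], y_test[:, j], config.threshold_step)
            )
    return {
        c: average_thresholds(v) if v else 0.5  # no usable fold: neutral default
        for c, v in per_class.items()
    }


def _train_level(
    notes: Sequence[OperativeNote],
    docs: list[TokenStream],
    label_sets: list[frozenset[str]],
    classes: Sequence[str],
    fold_of: np.ndarray,
    k: int,
    config: CascadeConfig,
    mode: str,
) -> LevelModel:
    thresholds = _fold_thresholds(docs, label_sets, classes, fold_of, k, config)
    tfidf = fit_tfidf(docs, config.max_features)
    X = transform_corpus(docs, tfidf)
    ovr = train_ovr(
        X, label_sets, classes,
        seed=config.seed, n_trees=config.n_trees,
        class_weighting=config.class_weighting, mode=mode,
    )
    ovr.thresholds = thresholds
    return LevelModel(tfidf=tfidf, ovr=ovr)


def train_cascade(
    notes: Sequence[OperativeNote],
    sections: Mapping[str, str],
    taxonomy: LabelTaxonomy = DEFAULT_TAXONOMY,
    config: CascadeConfig = CascadeConfig(),
) -> CascadeModel:
    """Train the full cascade from gold-labeled notes.

    ``sections`` maps note id -> extracted target-section text; notes without
    a parsed section or gold labels are ignored.  Conditional (subtype and
    technique) models are trained on the notes whose *gold* primary labels
    contain the parent class — ground-truth conditioning.  A conditional
    level observed with fewer than 2 classes is skipped (recorded in
    ``skipped_levels``).  Synthetic notes participate in training but are
    pinned to training folds during internal threshold selection.
    """
    from .evaluate import grouped_kfold, stratified_note_kfold  # lazy: avoid cycle

    usable = [
        n for n in notes
        if n.note_id in sections and n.gold_labels is not None
    ]
    if not usable:
        raise ValueError("no usable notes: need parsed sections and gold labels")
    docs = _tokenize_sections(usable, sections)
    primary_sets = [n.gold_labels.primary for n in usable]

    # primary: patient-grouped folds for threshold selection
    plan = grouped_kfold(
        [n.patient_id for n in usable], k=config.primary_folds, seed=config.seed,
        unit_ids=[n.note_id for n in usable],
        always_train=[n.note_id for n in usable if n.is_synthetic],
    )
    fold_of = np.array([plan.assignments[n.note_id] for n in usable])
    primary = _train_level(
        usable, docs, primary_sets, taxonomy.primary_classes,
        fold_of, config.primary_folds, config, mode="multilabel",
    )

    model = CascadeModel(taxonomy=taxonomy, config=config, primary=primary)

    for level, class_map, store in (
        ("subtype", taxonomy.subtype_classes, None),
        ("technique", taxonomy.technique_classes, None),
    ):
        for parent, classes in class_map.items():
            idx = []
            labels: list[frozenset[str]] = []
            for i, n in enumerate(usable):
                rec = n.gold_labels
                if parent not in rec.primary:
                    continue
                value = (rec.subtype if level == "subtype" else rec.technique).get(parent)
                if value is None:
                    continue
                idx.append(i)
                labels.append(frozenset({value}))
            observed = {next(iter(l)) for l in labels}
            if len(observed) < 2:
                model.skipped_levels.append(f"{level}:{parent}")
                continue
            # train only over classes observed in the data; taxonomy classes
            # with no examples cannot receive a scorer
            classes = tuple(c for c in classes if c in observed)
            sub_notes = [usable[i] for i in idx]
            sub_docs = [docs[i] for i in idx]
            plan = stratified_note_kfold(
                [next(iter(l)) for l in labels],
                k=config.conditional_folds, seed=config.seed,
                unit_ids=[n.note_id for n in sub_notes],
                always_train=[n.note_id for n in sub_notes if n.is_synthetic],
            )
            fold_of_sub = np.array([plan.assignments[n.note_id] for n in sub_notes])
            level_model = _train_level(
                sub_notes, sub_docs, labels, classes,
                fold_of_sub, config.conditional_folds, config, mode="single",
            )
            if level == "subtype":
                model.subtype_models[parent] = level_model
            else:
                model.technique_models[parent] = level_model
    return model


def classify_cascade(
    sections: Mapping[str, str],
    cascade: CascadeModel,
) -> dict[str, tuple[LabelRecord, dict]]:
    """Classify notes given their extracted target-section texts.

    Returns note id -> (taxonomy-valid LabelRecord, nested score dict).
    Subtype/technique models run only for *predicted* primary classes that
    have a trained conditional model.
    """
    note_ids = list(sections)
    docs = [preprocess(sections[nid], note_id=nid) for nid in note_ids]
    X = transform_corpus(docs, cascade.primary.tfidf)
    primary_scores, primary_preds = predict_primary(cascade.primary.ovr, X)

    results: dict[str, tuple[LabelRecord, dict]] = {}
    for i, nid in enumerate(note_ids):
        predicted = primary_preds[i]
        scores: dict = {
            "primary": {c: float(primary_scores[c][i]) for c in cascade.primary.ovr.classes},
            "subtype": {},
            "technique": {},
        }
        subtype: dict[str, str] = {}
        technique: dict[str, str] = {}
        for parent in sorted(predicted):
            sub_model = cascade.subtype_models.get(parent)
            if sub_model is not None:
                Xi = transform_corpus([docs[i]], sub_model.tfidf)
                s = sub_model.ovr.score(Xi)
                scores["subtype"][parent] = {c: float(s[c][0]) for c in sub_model.ovr.classes}
                subtype[parent] = sub_model.ovr.predict(Xi)[0]
            tech_model = cascade.technique_models.get(parent)
            if tech_model is not None:
                Xi = transform_corpus([docs[i]], tech_model.tfidf)
                s = tech_model.ovr.score(Xi)
                scores["technique"][parent] = {c: float(s[c][0]) for c in tech_model.ovr.classes}
                technique[parent] = tech_model.ovr.predict(Xi)[0]
        record = LabelRecord(
            primary=frozenset(predicted), subtype=subtype, technique=technique
        )
        cascade.taxonomy.validate_record(record)
        results[nid] = (record, scores)
    return results
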