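"""Sentence worthiness: abstract-driven annotation and the random-forest
good/bad classifier.

Training labels are produced without manual annotation: a sentence is
"good" (worth keeping for a summary) iff the Sørensen–Dice overlap
between its relevant-stem set and the relevant-stem set of the
article's abstract is at least a small threshold (default 0.01; the
comparison is a strict less-than on the bad side, so a sentence sitting
exactly at the threshold is good).

The classifier is a random forest over the six sentence indicators:
trees grown to purity on bootstrap samples, sqrt(#features) candidate
variables per split, class decided by majority vote with ties broken
toward "good" so that borderline sentences survive into the ranking
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FEATURE_NAMES, FeatureVector, dice_coefficient, feature_array
from .preprocess import ProcessedDocument

GOOD, BAD = "good", "bad"

DEFAULT_DS_THRESHOLD = 0.01
DEFAULT_N_TREES = 500
DEFAULT_SPLIT_FRACTION = 0.60


@dataclass
class AnnotationConfig:
    ds_threshold: float = DEFAULT_DS_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.ds_threshold <= 1.0:
            raise ValueError("ds_threshold must lie in [0, 1]")


@dataclass
class ModelReport:
    oob_accuracy: float
    test_accuracy: float
    per_class_accuracy: dict[str, float]
    balanced_accuracy: float
    n_train: int
    n_test: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class WorthinessModel:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...] = FEATURE_NAMES
    n_trees: int = DEFAULT_N_TREES
    seed: int = 0
    classes: tuple[str, str] = (BAD, GOOD)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "WorthinessModel":
        model = joblib.load(path)
        if not isinstance(model, WorthinessModel):
            raise ValueError(f"not a worthiness model file: {path}")
        return model


def annotate_by_abstract(
    doc: ProcessedDocument, cfg: AnnotationConfig | None = None
) -> list[str]:
    """Label each body sentence good/bad by Dice overlap with the abstract."""
    cfg = cfg or AnnotationConfig()
    abstract_set = doc.abstract_relevant_set
    if not doc.abstract_sentences:
        raise ValueError(
            f"document {doc.doc_id!r} has no abstract; cannot auto-annotate"
        )
    labels = []
    for s in doc.body_sentences:
        ds = dice_coefficient(abstract_set, s.relevant_set)
        labels.append(BAD if ds < cfg.ds_threshold else GOOD)
    return labels


def train_worthiness(
    features: list[FeatureVector] | np.ndarray,
    labels: list[str],
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> tuple[WorthinessModel, ModelReport]:
    """Train the forest on a stratified *split_fraction* of the sentences
    and report out-of-bag, held-out and per-class accuracies.

    Deterministic for a fixed seed.  Raises if only one class is present
    or if there are fewer than 10 sentences.
    """
    X = features if isinstance(features, np.ndarray) else feature_array(features)
    y = np.asarray(labels)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 labeled sentences to train")
    present = set(y.tolist())
    if len(present) < 2:
        raise ValueError(f"training labels contain a single class: {present}")

    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        train_size=split_fraction,
        stratify=y,
        random_state=seed,
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        min_samples_leaf=1,  # grow to purity
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_train, y_train)

    model = WorthinessModel(forest=forest, n_trees=n_trees, seed=seed)
    y_pred = predict_worthiness(model, X_test)
    test_acc = float(np.mean(np.asarray(y_pred) == y_test))
    per_class = {}
    for cls in sorted(present):
        mask = y_test == cls
        per_class[cls] = float(np.mean(np.asarray(y_pred)[mask] == cls))
    report = ModelReport(
        oob_accuracy=float(forest.oob_score_),
        test_accuracy=test_acc,
        per_class_accuracy=per_class,
        balanced_accuracy=float(np.mean(list(per_class.values()))),
        n_train=int(X_train.shape[0]),
        n_test=int(X_test.shape[0]),
    )
    return model, report


def predict_worthiness(
    model: WorthinessModel, features: list[FeatureVector] | np.ndarray
) -> list[str]:
    """Majority vote over the forest; an exact 50/50 tie goes to "good"."""
    X = features if isinstance(features, np.ndarray) else feature_array(features)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {len(model.feature_names)}"
        )
    proba = model.forest.predict_proba(X)
    good_idx = list(model.forest.classes_).index(GOOD)
    return [GOOD if p[good_idx] >= 0.5 else BAD for p in proba]
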