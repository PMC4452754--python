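"""Bag-of-words sentence classifiers with precision-targeted thresholds.

One linear max-margin (SVM) classifier per affective construct, trained on
token-count features, with:

* a Platt-style monotone score-to-probability mapping fitted on
  cross-validated decision scores (so probabilities are honest, not
  training-set artefacts);
* a single uncertainty-sampling active-learning round (the pool sentences
  with probability closest to 0.5 are sent to the oracle);
* threshold calibration: the smallest observed validation probability whose
  induced prediction set has precision >= the target (default 0.90).

Splits are by sentence-id hash (60/20/20 train/validation/reference) so they
are stable across runs; any overlap between training and evaluation ids is a
hard leakage error.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import LinearSVC

from .gazetteer import tokenize

__all__ = [
    "LabeledSet",
    "TrainedModel",
    "ThresholdedClassifier",
    "EvaluationResult",
    "TrainingError",
    "CalibrationError",
    "LeakageError",
    "featurize",
    "train",
    "active_learning_round",
    "evaluate",
    "calibrate_threshold",
    "split_by_hash",
    "train_construct_pipeline",
]


class TrainingError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class LeakageError(ValueError):
    pass


@dataclass
class LabeledSet:
    """Annotated sentences: parallel ids, texts and binary labels."""

    ids: np.ndarray
    texts: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.ids) == len(self.texts) == len(self.labels)):
            raise ValueError("ids, texts and labels must be parallel")

    def __len__(self):
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label") -> "LabeledSet":
        return cls(df["sentence_id"].to_numpy(), list(df["text"]), df[label_col].to_numpy())


def featurize(
    sentences: list[str], vocabulary: list[str] | None = None
) -> tuple:
    """Token-count matrix; vocabulary built from the data when not supplied.

    Prediction-time tokens outside the vocabulary are silently ignored.
    """
    vec = CountVectorizer(analyzer=tokenize, vocabulary=vocabulary)
    X = vec.fit_transform(sentences) if vocabulary is None else vec.transform(sentences)
    vocab = sorted(vec.vocabulary_, key=vec.vocabulary_.get)
    return X, vocab


@dataclass
class TrainedModel:
    """Linear separator over a fixed vocabulary plus monotone Platt mapping."""

    construct: str
    vocabulary: list[str]
    coef: np.ndarray
    intercept: float
    platt_a: float  # > 0, so probability is monotone in the raw score
    platt_b: float
    n_train: int
    seed: int
    train_ids: frozenset = field(default_factory=frozenset)

    def decision_function(self, sentences: list[str]) -> np.ndarray:
        X, _ = featurize(sentences, vocabulary=self.vocabulary)
        return X @ self.coef + self.intercept

    def predict_proba(self, sentences: list[str]) -> np.ndarray:
        from scipy.special import expit

        return expit(self.platt_a * self.decision_function(sentences) + self.platt_b)


@dataclass
class ThresholdedClassifier:
    model: TrainedModel
    threshold: float
    target_precision: float = 0.90

    def predict(self, sentences: list[str]) -> np.ndarray:
        return (self.model.predict_proba(sentences) >= self.threshold).astype(int)


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        # undefined when the classifier makes no positive calls
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def train(labeled: LabeledSet, seed: int = 0, C: float = 1.0, construct: str = "") -> TrainedModel:
    """Fit the linear SVM and its Platt probability mapping.

    The mapping is a 1-D logistic regression of held-out-fold decision scores
    on labels; its slope is required to be positive so the probability is
    monotone in the margin score.
    """
    y = labeled.labels
    if len(np.unique(y)) < 2:
        raise TrainingError("training data must contain both classes")
    X, vocab = featurize(labeled.texts)
    svm = LinearSVC(C=C, random_state=seed)
    n_splits = min(5, np.bincount(y).min())
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_predict(svm, X, y, cv=cv, method="decision_function")
    else:  # tiny sets: fall back to in-sample scores
        scores = svm.fit(X, y).decision_function(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(X, y)
    platt = LogisticRegression(C=1e3).fit(scores.reshape(-1, 1), y)
    a = float(platt.coef_[0, 0])
    b = float(platt.intercept_[0])
    if a <= 0:  # keep the monotonicity contract even on degenerate score sets
        a, b = 1.0, 0.0
    return TrainedModel(
        construct=construct,
        vocabulary=vocab,
        coef=np.asarray(svm.coef_).ravel(),
        intercept=float(svm.intercept_[0]),
        platt_a=a,
        platt_b=b,
        n_train=len(labeled),
        seed=seed,
        train_ids=frozenset(int(i) for i in labeled.ids),
    )


def active_learning_round(
    model: TrainedModel, pool: LabeledSet, k: int, labeled: LabeledSet
) -> LabeledSet:
    """One uncertainty-sampling round: label the k pool sentences nearest p=0.5.

    ``pool.labels`` plays the oracle (the annotator). Ties in |p - 0.5| break
    on the smaller sentence id. Returns the augmented labeled set.
    """
    if len(pool) == 0:
        warnings.warn("active-learning pool is empty; returning training set unchanged")
        return labeled
    k = min(k, len(pool))
    p = model.predict_proba(pool.texts)
    order = np.lexsort((pool.ids, np.abs(p - 0.5)))
    chosen = order[:k]
    return LabeledSet(
        np.concatenate([labeled.ids, pool.ids[chosen]]),
        labeled.texts + [pool.texts[i] for i in chosen],
        np.concatenate([labeled.labels, pool.labels[chosen]]),
    )


def _check_disjoint(train_ids: frozenset, eval_ids) -> None:
    overlap = train_ids & {int(i) for i in eval_ids}
    if overlap:
        raise LeakageError(
            f"{len(overlap)} sentence(s) appear in both training and evaluation sets"
        )


def evaluate(classifier: ThresholdedClassifier, reference: LabeledSet) -> EvaluationResult:
    """Confusion counts of thresholded predictions against reference labels."""
    _check_disjoint(classifier.model.train_ids, reference.ids)
    pred = classifier.predict(reference.texts)
    y = reference.labels
    return EvaluationResult(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
    )


def calibrate_threshold(
    model: TrainedModel, validation: LabeledSet, target: float = 0.90
) -> ThresholdedClassifier:
    """Smallest observed validation probability achieving the target precision."""
    if not 0 < target <= 1:
        raise ValueError("target precision must lie in (0, 1]")
    _check_disjoint(model.train_ids, validation.ids)
    p = model.predict_proba(validation.texts)
    y = validation.labels
    best = 0.0
    for theta in np.sort(np.unique(p)):
        pred = p >= theta
        n_pos = int(pred.sum())
        if n_pos == 0:
            continue
        precision = float(y[pred].sum()) / n_pos
        best = max(best, precision)
        if precision >= target:
            return ThresholdedClassifier(model, float(theta), target)
    raise CalibrationError(
        f"no threshold attains precision {target:.2f}; best achievable {best:.3f}"
    )


def split_by_hash(ids, fractions=(0.6, 0.2, 0.2)) -> np.ndarray:
    """Stable train/validation/reference split by sentence-id hash.

    Returns an array of {'train','validation','reference'} aligned with ids.
    """
    edges = np.cumsum(np.asarray(fractions) * 100.0)
    names = np.array(["train", "validation", "reference"])
    buckets = np.array(
        [
            int(hashlib.md5(str(int(i)).encode()).hexdigest(), 16) % 100
            for i in np.asarray(ids)
        ]
    )
    return names[np.searchsorted(edges, buckets, side="right")]


def train_construct_pipeline(
    corpus: pd.DataFrame,
    construct: str,
    seed: int = 0,
    initial_frac: float = 0.5,
    al_k: int = 100,
    target_precision: float = 0.90,
    C: float = 1.0,
) -> dict:
    """Full per-construct workflow: split, train, one AL round, calibrate, test.

    ``corpus`` must have sentence_id / construct / text / label columns (the
    label column stands in for the human annotator). Returns the calibrated
    classifier plus baseline (theta = 0.5) and thresholded evaluations.
    """
    sub = corpus[corpus["construct"] == construct].reset_index(drop=True)
    if sub.empty:
        raise TrainingError(f"no sentences for construct {construct!r}")
    split = split_by_hash(sub["sentence_id"])
    train_df = sub[split == "train"]
    val_df = sub[split == "validation"]
    ref_df = sub[split == "reference"]

    rng = np.random.default_rng(seed)
    n_init = max(2, int(round(initial_frac * len(train_df))))
    init_idx = np.sort(rng.choice(len(train_df), size=n_init, replace=False))
    labeled = LabeledSet.from_frame(train_df.iloc[init_idx])
    pool_df = train_df.drop(train_df.index[init_idx])
    pool = LabeledSet.from_frame(pool_df)

    initial_model = train(labeled, seed=seed, C=C, construct=construct)
    augmented = active_learning_round(initial_model, pool, al_k, labeled)
    model = train(augmented, seed=seed, C=C, construct=construct)

    validation = LabeledSet.from_frame(val_df)
    reference = LabeledSet.from_frame(ref_df)
    clf = calibrate_threshold(model, validation, target=target_precision)
    return {
        "construct": construct,
        "classifier": clf,
        "model": model,
        "evaluation": evaluate(clf, reference),
        "baseline_evaluation": evaluate(ThresholdedClassifier(model, 0.5), reference),
        "n_train": len(augmented),
        "n_validation": len(validation),
        "n_reference": len(reference),
    }


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

ARCHIVE_VERSION = 1


def save_classifier(clf: ThresholdedClassifier, path) -> None:
    payload = {
        "version": ARCHIVE_VERSION,
        "construct": clf.model.construct,
        "vocabulary": clf.model.vocabulary,
        "coef": clf.model.coef.tolist(),
        "intercept": clf.model.intercept,
        "platt_a": clf.model.platt_a,
        "platt_b": clf.model.platt_b,
        "n_train": clf.model.n_train,
        "seed": clf.model.seed,
        "train_ids": sorted(clf.model.train_ids),
        "threshold": clf.threshold,
        "target_precision": clf.target_precision,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path) -> ThresholdedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError("unsupported classifier archive version")
    model = TrainedModel(
        construct=payload["construct"],
        vocabulary=payload["vocabulary"],
        coef=np.asarray(payload["coef"]),
        intercept=payload["intercept"],
        platt_a=payload["platt_a"],
        platt_b=payload["platt_b"],
        n_train=payload["n_train"],
        seed=payload["seed"],
        train_ids=frozenset(payload["train_ids"]),
    )
    return ThresholdedClassifier(model, payload["threshold"], payload["target_precision"])
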