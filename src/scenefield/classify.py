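"""Linear max-margin scene classifier on GIST features.

The classifier is trained once per task on clean (noise-free, unoccluded)
features and then evaluated on degraded stimuli.  Its sensitivity under
degradation is estimated either from the Gaussian-decision-value route
(assuming normally distributed classifier output per class) or from its
hit/false-alarm rates like a human observer.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .sdt import compute_dprime
from .types import ConfusionCounts


@dataclass
class TrainedClassifier:
    """Linear separator with training-set feature standardization."""

    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    task: Optional[str] = None
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weight vector must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.size

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "task": self.task,
            "training_manifest": self.training_manifest,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_scale=np.asarray(payload["feature_scale"], dtype=float),
            task=payload.get("task"),
            training_manifest=payload.get("training_manifest", {}),
        )


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float = 1.0,
    task: Optional[str] = None,
    manifest: Optional[dict] = None,
) -> TrainedClassifier:
    """Soft-margin linear SVM with training-set standardization.

    Standardization statistics come from the training set only; zero-variance
    features get unit scale so they contribute nothing after centring.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or np.any(counts < 2):
        raise ValueError("training needs >= 2 examples of each of two classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < np.finfo(float).eps, 1.0, sd)
    Z = (X - mu) / sd
    svm = LinearSVC(C=regularization, dual=False, tol=1e-6, max_iter=20000)
    svm.fit(Z, y)
    return TrainedClassifier(
        weights=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        feature_mean=mu,
        feature_scale=sd,
        task=task,
        training_manifest=manifest or {},
    )


def predict(model: TrainedClassifier, features: np.ndarray):
    """Decision values and labels: dv = w . z + b; label 1 iff dv > 0.

    A decision value of exactly 0 is assigned to the reference class 0.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} != model's {model.n_features}"
        )
    Z = (X - model.feature_mean) / model.feature_scale
    dv = Z @ model.weights + model.intercept
    labels = (dv > 0).astype(int)
    return labels, dv


@dataclass
class SplitAssignment:
    """Per-participant stimulus assignment shared by observer and model."""

    participant_id: str
    stimuli: dict[str, list[int]]   # condition -> stimulus indices into pool
    seed: int


def semi_random_split(
    pool_labels: Sequence[int],
    participants: Sequence[str],
    conditions: Sequence[str],
    n_per_condition: int,
    seed: int,
) -> list[SplitAssignment]:
    """Individually randomized, label-balanced stimulus samples.

    Each participant x condition receives ``n_per_condition`` stimuli sampled
    without replacement, balanced across the two labels.  Assignments are
    disjoint across a participant's conditions, and across participants as
    long as the pool permits; when the pool is exhausted it is refilled
    excluding only the current participant's own stimuli.
    """
    y = np.asarray(pool_labels, dtype=int)
    by_label = {lab: list(np.flatnonzero(y == lab)) for lab in (0, 1)}
    n_half = n_per_condition // 2
    n_rest = n_per_condition - n_half
    need = len(conditions) * max(n_half, n_rest)
    for lab in (0, 1):
        if len(by_label[lab]) < need:
            raise ValueError(
                "stimulus pool too small for a disjoint per-participant split"
            )
    rng = np.random.default_rng(seed)
    remaining = {lab: set(by_label[lab]) for lab in (0, 1)}
    assignments = []
    for pid in participants:
        own: set[int] = set()
        stim: dict[str, list[int]] = {}
        for cond_i, cond in enumerate(conditions):
            take = []
            for lab, n_lab in ((0, n_half), (1, n_rest)):
                if len(remaining[lab]) < n_lab:  # refill, excluding own draws
                    remaining[lab] = set(by_label[lab]) - own
                    if len(remaining[lab]) < n_lab:
                        raise ValueError("stimulus pool exhausted")
                chosen = rng.choice(sorted(remaining[lab]), size=n_lab,
                                    replace=False)
                remaining[lab] -= set(int(i) for i in chosen)
                own |= set(int(i) for i in chosen)
                take.extend(int(i) for i in chosen)
            rng.shuffle(take)
            stim[cond] = take
        assignments.append(SplitAssignment(participant_id=pid, stimuli=stim,
                                           seed=seed))
    return assignments


def classifier_confusion(
    model: TrainedClassifier, features: np.ndarray, labels: Sequence[int]
) -> ConfusionCounts:
    """Confusion counts of the classifier treated as a binary observer."""
    pred, _ = predict(model, features)
    y = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        hits=int(np.sum((y == 1) & (pred == 1))),
        misses=int(np.sum((y == 1) & (pred == 0))),
        false_alarms=int(np.sum((y == 0) & (pred == 1))),
        correct_rejections=int(np.sum((y == 0) & (pred == 0))),
    )


def estimate_model_sensitivity(
    model: TrainedClassifier,
    features_by_condition: Mapping[str, np.ndarray],
    labels_by_condition: Mapping[str, Sequence[int]],
    method: Literal["gaussian_decision_values", "rate_based"]
    = "gaussian_decision_values",
) -> dict[str, float]:
    """Estimated sensitivity d_hat of the classifier per condition.

    ``gaussian_decision_values`` (default) assumes the classifier output is
    normally distributed per class even under heavy degradation:
    d_hat = (mean(dv | 1) - mean(dv | 0)) / sqrt((var0 + var1) / 2).
    ``rate_based`` computes d' from the classifier's hit/false-alarm rates
    with the extreme-rate correction, like a human observer.
    """
    out: dict[str, float] = {}
    for cond, X in features_by_condition.items():
        y = np.asarray(labels_by_condition[cond], dtype=int)
        if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
            raise ValueError(
                f"condition {cond!r} needs >= 2 stimuli per class"
            )
        if method == "gaussian_decision_values":
            _, dv = predict(model, X)
            dv0, dv1 = dv[y == 0], dv[y == 1]
            pooled_sd = np.sqrt((dv0.var(ddof=1) + dv1.var(ddof=1)) / 2.0)
            if pooled_sd < np.finfo(float).eps:
                out[cond] = 0.0
            else:
                out[cond] = float((dv1.mean() - dv0.mean()) / pooled_sd)
        elif method == "rate_based":
            out[cond] = compute_dprime(classifier_confusion(model, X, y)).d_prime
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def classifier_bias(
    model: TrainedClassifier,
    features: np.ndarray,
    labels: Sequence[int],
) -> dict[str, float]:
    """Both bias readings: decision-threshold criterion and rate-based c."""
    _, dv = predict(model, features)
    y = np.asarray(labels, dtype=int)
    dv0, dv1 = dv[y == 0], dv[y == 1]
    pooled_sd = np.sqrt((dv0.var(ddof=1) + dv1.var(ddof=1)) / 2.0)
    if pooled_sd < np.finfo(float).eps:
        c_dv = 0.0
    else:
        # distance of the decision threshold (dv = 0) from the class midpoint
        c_dv = float(-(dv0.mean() + dv1.mean()) / (2.0 * pooled_sd))
    c_rate = compute_dprime(classifier_confusion(model, features, y)).criterion_c
    return {"criterion_decision_values": c_dv, "criterion_rate_based": c_rate}
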