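"""One-against-one Gaussian-kernel SVM with an interval decision rule.

Five gaze states yield C(5,2) = 10 binary soft-margin SVMs.  Each binary
problem is solved by scikit-learn's SMO on a precomputed Gram matrix built
from this module's own Gaussian kernel

    k(x, x') = exp(−‖x − x'‖² / (2σ²)).

At prediction time the ten binary votes are aggregated to a scalar score

    V = Σ_k w_k · m_k,   w_k = (votes for k among the plurality winner's
                                four contests) / 4

where each class's interval midpoint m_k is: up +0.5, down −0.5, left +1.5,
right −1.5, straight 0.  Restricting the vote shares to the pairs that
involve the plurality winner makes every clean sweep land exactly on the
winner's midpoint, while contested patterns interpolate toward the
challengers' midpoints; pairs between two far-away classes (whose vote for
an out-of-distribution vector is essentially arbitrary) cannot perturb V.
A tied plurality averages the tied classes' scores, so a fully symmetric
vote pattern yields V = 0.  V is then discretized by open intervals —
up (0, 1), down (−1, 0), left (1, 2), right (−2, −1) — with values on an
interval boundary (within tolerance ε) read as straight gaze.  A trial in
which neither channel produced any event short-circuits to straight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .features import FEATURE_LENGTH, FeatureNormalizer
from .synth import STATES

MODEL_FORMAT_VERSION = 1

#: Interval midpoints of the decision rule, per state.
INTERVAL_MIDPOINTS: Dict[str, float] = {
    "straight": 0.0, "up": 0.5, "down": -0.5, "left": 1.5, "right": -1.5,
}

#: Open decision intervals per directional state.
DECISION_INTERVALS: Dict[str, Tuple[float, float]] = {
    "up": (0.0, 1.0), "down": (-1.0, 0.0), "left": (1.0, 2.0), "right": (-2.0, -1.0),
}

_BOUNDARIES = (-2.0, -1.0, 0.0, 1.0, 2.0)


class UntrainedModelError(ValueError):
    """Raised when prediction is attempted on an untrained model."""


def gaussian_kernel(x: np.ndarray, x_prime: np.ndarray, sigma: float) -> float:
    """Gaussian (RBF) similarity exp(−‖x−x′‖²/2σ²) in (0, 1]."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError("feature vectors must have equal length")
    d2 = float(np.sum((x - x_prime) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma ** 2)))


def gaussian_gram(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix of the Gaussian kernel between row sets ``a`` and ``b``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    d2 = cdist(np.atleast_2d(a), np.atleast_2d(b), metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma ** 2))


def median_heuristic_sigma(z: np.ndarray) -> float:
    """Median of the non-zero pairwise distances (fallback 1.0)."""
    d = cdist(z, z)
    upper = d[np.triu_indices_from(d, k=1)]
    upper = upper[upper > 0]
    return float(np.median(upper)) if upper.size else 1.0


@dataclass
class BinarySVM:
    """Support vectors, dual weights and bias of one trained pair classifier.

    ``classes`` is the (negative, positive) state pair in SVC convention:
    a positive decision value votes for ``classes[1]``.
    """

    classes: Tuple[str, str]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def decision_value(self, z: np.ndarray, sigma: float) -> float:
        k = gaussian_gram(np.atleast_2d(z), self.support_vectors, sigma)
        return float((k @ self.dual_coef)[0] + self.intercept)

    def vote(self, z: np.ndarray, sigma: float) -> str:
        return self.classes[1] if self.decision_value(z, sigma) > 0 else self.classes[0]


@dataclass
class TrainedModel:
    """Ten one-against-one classifiers plus the interval decision rule."""

    binaries: List[BinarySVM] = field(default_factory=list)
    sigma: float = 1.0
    penalty: float = 1.0
    normalizer: FeatureNormalizer = field(default_factory=FeatureNormalizer.identity)
    classes: Tuple[str, ...] = STATES
    epsilon: float = 0.05
    format_version: int = MODEL_FORMAT_VERSION

    @property
    def is_trained(self) -> bool:
        return len(self.binaries) > 0

    def to_json(self) -> str:
        return json.dumps({
            "format_version": self.format_version,
            "sigma": self.sigma,
            "penalty": self.penalty,
            "epsilon": self.epsilon,
            "classes": list(self.classes),
            "normalizer": self.normalizer.to_dict(),
            "binaries": [{
                "classes": list(b.classes),
                "support_vectors": b.support_vectors.tolist(),
                "dual_coef": b.dual_coef.tolist(),
                "intercept": b.intercept,
            } for b in self.binaries],
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version "
                             f"{d.get('format_version')!r}")
        return cls(
            binaries=[BinarySVM(classes=tuple(b["classes"]),
                                support_vectors=np.asarray(b["support_vectors"]),
                                dual_coef=np.asarray(b["dual_coef"]),
                                intercept=float(b["intercept"]))
                      for b in d["binaries"]],
            sigma=float(d["sigma"]),
            penalty=float(d["penalty"]),
            epsilon=float(d["epsilon"]),
            classes=tuple(d["classes"]),
            normalizer=FeatureNormalizer.from_dict(d["normalizer"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(features: np.ndarray, labels: Sequence[str], sigma: Optional[float] = None,
          penalty: float = 1.0, epsilon: float = 0.05, seed: int = 0,
          classes: Optional[Sequence[str]] = None) -> TrainedModel:
    """Fit one binary Gaussian-kernel SVM per class pair.

    ``features`` is the raw (pre-normalization) feature matrix; a z-scoring
    normalizer is fitted here and stored with the model.  ``sigma`` defaults
    to the median pairwise distance over the normalized training set.
    Training is deterministic for fixed inputs (``seed`` is accepted for
    interface stability; the SMO solve itself has no random component).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != FEATURE_LENGTH:
        raise ValueError(f"features must be (n, {FEATURE_LENGTH}), got {x.shape}")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    if classes is None:
        classes = tuple(s for s in STATES if s in set(y))
        missing = set(y) - set(STATES)
        if missing:
            raise ValueError(f"unknown labels: {sorted(missing)}")
    else:
        classes = tuple(classes)
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} needs at least 2 training samples")
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    if penalty <= 0:
        raise ValueError("penalty must be positive")

    normalizer = FeatureNormalizer.fit(x)
    z = np.vstack([normalizer.transform(row) for row in x])
    if sigma is None:
        sigma = median_heuristic_sigma(z)
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    binaries: List[BinarySVM] = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            neg, pos = classes[i], classes[j]
            sel = (y == neg) | (y == pos)
            zi = z[sel]
            # 0/1 coding keeps SVC's (negative, positive) class order explicit.
            yi = (y[sel] == pos).astype(int)
            gram = gaussian_gram(zi, zi, sigma)
            svc = SVC(kernel="precomputed", C=penalty, tol=1e-8)
            svc.fit(gram, yi)
            binaries.append(BinarySVM(
                classes=(neg, pos),
                support_vectors=zi[svc.support_],
                dual_coef=svc.dual_coef_.ravel(),
                intercept=float(svc.intercept_[0]),
            ))
    return TrainedModel(binaries=binaries, sigma=float(sigma), penalty=penalty,
                        normalizer=normalizer, classes=classes, epsilon=epsilon)


def pair_outcomes(model: TrainedModel,
                  raw_features: np.ndarray) -> Dict[Tuple[str, str], str]:
    """Winner of each one-against-one contest for one trial."""
    if not model.is_trained:
        raise UntrainedModelError("model has no trained binary classifiers")
    z = model.normalizer.transform(raw_features)
    return {b.classes: b.vote(z, model.sigma) for b in model.binaries}


def vote_counts(model: TrainedModel, raw_features: np.ndarray) -> Dict[str, int]:
    """Per-class votes of the one-against-one classifiers for one trial."""
    counts = {c: 0 for c in model.classes}
    for winner in pair_outcomes(model, raw_features).values():
        counts[winner] += 1
    return counts


def score_from_outcomes(outcomes: Dict[Tuple[str, str], str],
                        midpoints: Dict[str, float] = INTERVAL_MIDPOINTS,
                        ) -> float:
    """Aggregate pairwise winners to the scalar score V = Σ_k w_k·m_k.

    The vote shares w_k are taken over the four contests involving the
    plurality winner, so a class sweeping its pairs lands exactly on its
    interval midpoint m_k regardless of how the unrelated pairs voted.
    A tied plurality averages the tied classes' scores; fully symmetric
    patterns therefore cancel to 0 (straight).
    """
    counts: Dict[str, int] = {}
    for (neg, pos), winner in outcomes.items():
        if winner not in (neg, pos):
            raise ValueError(f"winner {winner!r} not in pair ({neg!r}, {pos!r})")
        counts[winner] = counts.get(winner, 0) + 1
        counts.setdefault(neg, 0)
        counts.setdefault(pos, 0)
    if not counts:
        raise ValueError("no pairwise outcomes supplied")
    top = max(counts.values())
    tied = [c for c, v in counts.items() if v == top]
    scores = []
    for c in tied:
        own = [(pair, w) for pair, w in outcomes.items() if c in pair]
        if not own:
            continue
        scores.append(sum(midpoints[w] for _, w in own) / len(own))
    return float(np.mean(scores)) if scores else 0.0


def decision_score(model: TrainedModel, raw_features: np.ndarray) -> float:
    """The scalar decision score V ∈ [−2, 2] for one trial."""
    return score_from_outcomes(pair_outcomes(model, raw_features))


def interval_decision(v: float, epsilon: float = 0.05) -> str:
    """Map V to a gaze state by the open-interval rule.

    Values within ``epsilon`` of any interval boundary (−2, −1, 0, 1, 2) are
    read as straight gaze.
    """
    for b in _BOUNDARIES:
        if abs(v - b) <= epsilon:
            return "straight"
    for state, (lo, hi) in DECISION_INTERVALS.items():
        if lo < v < hi:
            return state
    return "straight"  # |V| beyond 2: no directional interval contains it


def classify(model: TrainedModel, raw_features: np.ndarray) -> str:
    """Predict the gaze state for one trial's raw feature vector.

    Event-free trials (both channel counts zero before normalization)
    short-circuit to straight without consulting the classifiers.
    """
    if not model.is_trained:
        raise UntrainedModelError("model has no trained binary classifiers")
    raw = np.asarray(raw_features, dtype=float)
    if raw[3] == 0 and raw[7] == 0:
        return "straight"
    v = decision_score(model, raw)
    return interval_decision(v, model.epsilon)


def predict(model: TrainedModel, feature_matrix: np.ndarray) -> List[str]:
    """Classify each row of a raw feature matrix."""
    return [classify(model, row) for row in np.atleast_2d(feature_matrix)]
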