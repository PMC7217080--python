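"""One-level decision trees (decision stumps) split on Gini impurity.

Each stump thresholds a single scalar feature.  The split threshold is the
midpoint between consecutive distinct sorted feature values that minimizes
the weighted Gini diversity index of the two children; each child predicts
its majority class and reports the majority fraction as the class
probability.  Conventions (deterministic by design):

* feature < threshold goes left, feature >= threshold goes right;
* Gini ties between candidate splits: the smallest threshold wins;
* majority ties within a child: class 0 (insoluble), probability 0.5;
* if no split lowers impurity below the root's, the stump degenerates to a
  single leaf predicting the root majority class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np


class StumpError(ValueError):
    pass


@dataclass
class DecisionStump:
    """A fitted one-split tree on a single feature (see module docstring)."""

    scale_id: str
    threshold: Optional[float]
    left_class: int
    right_class: int
    left_prob: float
    right_prob: float
    is_leaf_only: bool
    training_accuracy: float

    def predict(self, feature: float) -> tuple[int, float]:
        return stump_predict(self, feature)

    def predict_array(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized prediction: (classes, probabilities) for a feature vector."""
        features = np.asarray(features, dtype=float)
        if not np.all(np.isfinite(features)):
            raise StumpError("non-finite feature value")
        if self.is_leaf_only:
            cls = np.full(features.shape, self.left_class, dtype=int)
            prob = np.full(features.shape, self.left_prob, dtype=float)
            return cls, prob
        left = features < self.threshold
        cls = np.where(left, self.left_class, self.right_class)
        prob = np.where(left, self.left_prob, self.right_prob)
        return cls, prob

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "DecisionStump":
        return cls(**json.loads(payload))


def _majority(labels: np.ndarray) -> tuple[int, float]:
    """Majority class and its fraction; ties predict class 0."""
    p1 = labels.mean()
    if p1 > 0.5:
        return 1, float(p1)
    return 0, float(1.0 - p1)


def _gini(labels: np.ndarray) -> float:
    p1 = labels.mean()
    return float(1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1))


def fit_stump(features, labels, scale_id: str = "") -> DecisionStump:
    """Fit a decision stump minimizing weighted Gini impurity.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted feature values.  With no informative split (pure node, all
    features identical, or no candidate improving on the root) the stump is
    leaf-only and predicts the root majority class.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 1 or x.shape != y.shape:
        raise StumpError("features and labels must be equal-length 1-D vectors")
    if x.size == 0:
        raise StumpError("empty training data")
    if not np.all(np.isfinite(x)):
        raise StumpError("non-finite feature value")
    if not np.isin(y, (0, 1)).all():
        raise StumpError("labels must be binary 0/1")

    n = x.size
    root_class, root_frac = _majority(y)
    root_gini = _gini(y)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # split after position i (0-based) is valid where the value changes
    boundary = np.nonzero(np.diff(xs) > 0)[0]

    leaf = DecisionStump(
        scale_id=scale_id, threshold=None,
        left_class=root_class, right_class=root_class,
        left_prob=root_frac, right_prob=root_frac,
        is_leaf_only=True, training_accuracy=root_frac)
    if boundary.size == 0 or root_gini == 0.0:
        return leaf

    cum1 = np.cumsum(ys)  # ones in the first i+1 sorted points
    n_left = boundary + 1
    n_right = n - n_left
    ones_left = cum1[boundary]
    ones_right = cum1[-1] - ones_left
    p1l = ones_left / n_left
    p1r = ones_right / n_right
    gini_left = 1.0 - p1l ** 2 - (1.0 - p1l) ** 2
    gini_right = 1.0 - p1r ** 2 - (1.0 - p1r) ** 2
    weighted = (n_left * gini_left + n_right * gini_right) / n

    # smallest threshold among numerically tied minima
    best = int(np.nonzero(weighted <= weighted.min() + 1e-12)[0][0])
    if weighted[best] >= root_gini - 1e-12:
        return leaf

    i = boundary[best]
    threshold = float((xs[i] + xs[i + 1]) / 2.0)
    yl, yr = ys[: i + 1], ys[i + 1:]
    left_class, left_prob = _majority(yl)
    right_class, right_prob = _majority(yr)
    correct = (yl == left_class).sum() + (yr == right_class).sum()
    return DecisionStump(
        scale_id=scale_id, threshold=threshold,
        left_class=left_class, right_class=right_class,
        left_prob=left_prob, right_prob=right_prob,
        is_leaf_only=False, training_accuracy=float(correct / n))


def stump_predict(stump: DecisionStump, feature: float) -> tuple[int, float]:
    """Class decision and child-node probability for one feature value.

    ``feature < threshold`` goes to the left child; the boundary value
    itself goes right.  Leaf-only stumps return the root majority vote.
    """
    if not np.isfinite(feature):
        raise StumpError(f"non-finite feature {feature!r}")
    if stump.is_leaf_only:
        return stump.left_class, stump.left_prob
    if feature < stump.threshold:
        return stump.left_class, stump.left_prob
    return stump.right_class, stump.right_prob


def stump_training_accuracy(stump: DecisionStump, features, labels) -> float:
    """Fraction of labels the stump reproduces (its feature importance)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.size == 0:
        raise StumpError("empty evaluation data")
    cls, _ = stump.predict_array(x)
    return float((cls == y).mean())
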