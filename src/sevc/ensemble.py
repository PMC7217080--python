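"""The soft ensemble vote classifier (sEVC).

One decision stump is induced per hydrophobicity scale.  Each stump's
*feature importance* is its accuracy on the data it was trained on; stumps
are sorted by descending importance (stable on ties, so earlier library
scales win).  A model with ``k`` included classifiers uses the top ``k``
stumps: each contributes its class probability to the score of its decided
class only, and the class with the larger summed score is elected.  Ties
elect class 0 (insoluble) — the conservative call in a solubility screen.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .scales import ScaleLibrary
from .stump import DecisionStump, fit_stump


class EnsembleError(ValueError):
    pass


@dataclass
class EnsembleModel:
    """Importance-sorted stumps plus provenance of the feature window."""

    stumps: list[DecisionStump]          # descending feature importance
    importances: list[float]             # parallel to stumps
    trim_n: int = 0
    trim_c: int = 0
    k: int = field(default=0)            # default included count (0 => all)

    def __post_init__(self) -> None:
        if len(self.stumps) != len(self.importances):
            raise EnsembleError("stumps and importances length mismatch")
        if any(b > a + 1e-12 for a, b in
               zip(self.importances, self.importances[1:])):
            raise EnsembleError("importances must be non-increasing")
        if self.k == 0:
            self.k = len(self.stumps)
        if not (1 <= self.k <= len(self.stumps)):
            raise EnsembleError(f"k={self.k} outside 1..{len(self.stumps)}")

    @property
    def scale_ids(self) -> list[str]:
        return [s.scale_id for s in self.stumps]

    def to_json(self) -> str:
        return json.dumps({
            "trim_n": self.trim_n, "trim_c": self.trim_c, "k": self.k,
            "importances": self.importances,
            "stumps": [asdict(s) for s in self.stumps]})

    @classmethod
    def from_json(cls, payload: str) -> "EnsembleModel":
        data = json.loads(payload)
        return cls(
            stumps=[DecisionStump(**s) for s in data["stumps"]],
            importances=data["importances"],
            trim_n=data["trim_n"], trim_c=data["trim_c"], k=data["k"])


def train_ensemble(fm: FeatureMatrix, labels,
                   library: ScaleLibrary | None = None) -> EnsembleModel:
    """Fit one stump per scale column and sort by feature importance.

    Importance is the stump's training-set accuracy.  The sort is stable,
    so equal importances keep library (column) order.  Degenerate columns
    yield leaf-only stumps that stay in the ensemble.
    """
    y = np.asarray(labels, dtype=int)
    if y.size != len(fm.frame):
        raise EnsembleError("labels length does not match feature matrix")
    scale_ids = library.ids if library is not None else fm.scale_ids
    stumps = []
    for sid in scale_ids:
        stumps.append(fit_stump(fm.column(sid), y, scale_id=sid))
    order = sorted(range(len(stumps)),
                   key=lambda i: -stumps[i].training_accuracy)
    stumps = [stumps[i] for i in order]
    return EnsembleModel(
        stumps=stumps,
        importances=[s.training_accuracy for s in stumps],
        trim_n=fm.trim_n, trim_c=fm.trim_c)


def _features_for(model: EnsembleModel, features, k: int) -> list[float]:
    if not (1 <= k <= len(model.stumps)):
        raise EnsembleError(f"k={k} outside 1..{len(model.stumps)}")
    out = []
    for stump in model.stumps[:k]:
        try:
            out.append(float(features[stump.scale_id]))
        except KeyError:
            raise EnsembleError(
                f"missing feature for included scale {stump.scale_id!r}") from None
    return out


def soft_vote(model: EnsembleModel, features, k: int | None = None
              ) -> tuple[int, float, float]:
    """Soft ensemble vote of the top ``k`` stumps on one observation.

    ``features`` maps scale id to feature value (dict or pandas Series).
    Each stump adds its child-node probability to its decided class's
    score; returns ``(elected_class, score0, score1)`` with ties electing
    class 0.
    """
    k = model.k if k is None else k
    vals = _features_for(model, features, k)
    score = [0.0, 0.0]
    for stump, val in zip(model.stumps[:k], vals):
        cls, prob = stump.predict(val)
        score[cls] += prob
    elected = 1 if score[1] > score[0] else 0
    return elected, score[0], score[1]


def hard_vote(model: EnsembleModel, features, k: int | None = None) -> int:
    """Majority vote: the soft vote with every probability set to 1."""
    k = model.k if k is None else k
    vals = _features_for(model, features, k)
    count = [0, 0]
    for stump, val in zip(model.stumps[:k], vals):
        cls, _ = stump.predict(val)
        count[cls] += 1
    return 1 if count[1] > count[0] else 0


def predict_dataset(model: EnsembleModel, fm: FeatureMatrix,
                    k: int | None = None) -> pd.DataFrame:
    """Row-wise soft vote over a feature matrix (vectorized over stumps).

    Returns a DataFrame indexed by construct id with columns
    ``predicted``, ``score0``, ``score1``.
    """
    k = model.k if k is None else k
    if not (1 <= k <= len(model.stumps)):
        raise EnsembleError(f"k={k} outside 1..{len(model.stumps)}")
    n = len(fm.frame)
    score0 = np.zeros(n)
    score1 = np.zeros(n)
    for stump in model.stumps[:k]:
        if stump.scale_id not in fm.frame.columns:
            raise EnsembleError(
                f"feature matrix lacks included scale {stump.scale_id!r}")
        cls, prob = stump.predict_array(fm.column(stump.scale_id))
        score0 += np.where(cls == 0, prob, 0.0)
        score1 += np.where(cls == 1, prob, 0.0)
    predicted = (score1 > score0).astype(int)
    return pd.DataFrame(
        {"predicted": predicted, "score0": score0, "score1": score1},
        index=fm.frame.index)
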