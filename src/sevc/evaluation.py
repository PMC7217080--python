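"""Model evaluation: metrics, sampling, cross-validation, learning curves.

Metrics are Matthews' correlation coefficient (MCC) and accuracy; summary
statistics are the median and the unscaled median absolute deviation (MAD).
Training sets are drawn either by capped stratified sampling over the
insert x strategy grid, or plain random subsampling.  Model selection uses
Monte Carlo cross-validation (repeated random 50/50 splits, with feature
selection redone inside every split).  The learning experiment maps model
performance over training-set size and number of included classifiers, and
the misclassification table aggregates per-strategy classification-group
frequencies across many models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import Dataset, FeatureMatrix, build_feature_matrix, kr_ratio
from .scales import ScaleLibrary, charge_scale
from .stump import DecisionStump, fit_stump
from .ensemble import EnsembleModel, predict_dataset, train_ensemble

GROUPS = ("TP", "TN", "FP", "FN")


class EvaluationError(ValueError):
    pass


class UndefinedMCCError(EvaluationError):
    """MCC denominator has a zero factor; the coefficient is undefined."""


class InfeasibleSamplingError(EvaluationError):
    """Stratum caps cannot accommodate the requested training-set size."""


# ---------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-classification counts (positive = soluble = class 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("negative count in confusion matrix")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise EvaluationError("label vectors differ in length")
        return cls(tp=int(((t == 1) & (p == 1)).sum()),
                   tn=int(((t == 0) & (p == 0)).sum()),
                   fp=int(((t == 0) & (p == 1)).sum()),
                   fn=int(((t == 1) & (p == 0)).sum()))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews' correlation coefficient.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, in [-1, 1].
    Undefined (raises) when any denominator factor is zero.
    """
    f1 = cm.tp + cm.fp
    f2 = cm.tp + cm.fn
    f3 = cm.tn + cm.fp
    f4 = cm.tn + cm.fn
    if 0 in (f1, f2, f3, f4):
        raise UndefinedMCCError(
            f"zero denominator factor for {cm}; MCC undefined")
    num = cm.tp * cm.tn - cm.fp * cm.fn
    return float(num / math.sqrt(float(f1) * f2 * f3 * f4))


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / total."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def _mcc_or_nan(cm: ConfusionMatrix) -> float:
    try:
        return mcc(cm)
    except UndefinedMCCError:
        return float("nan")


def median_mad(values) -> tuple[float, float]:
    """Median and unscaled MAD, ``median(|x - median(x)|)``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EvaluationError("empty value vector")
    med = float(np.median(arr))
    return med, float(np.median(np.abs(arr - med)))


# ------------------------------------------------------------- sampling

def _child_seeds(seed: int, n: int) -> list[int]:
    """Expand one master seed into n reproducible child seeds (< 2**31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def stratified_sample(ds: Dataset, n_train: int, seed: int,
                      max_attempts: int = 100) -> tuple[Dataset, Dataset]:
    """Draw ``n_train`` records with per-insert and per-strategy caps.

    Each insert may occur at most ``ceil(n_train / n_inserts)`` times and
    each strategy at most ``ceil(n_train / n_strategies)`` times.  Records
    are drawn one by one uniformly at random without replacement; once a
    stratum reaches its cap all its remaining records become unavailable.
    A draw that dead-ends is restarted with the next child seed.

    Returns ``(train, rest)``; ``rest`` is the complement in original order.
    """
    n = len(ds)
    if n_train > n:
        raise InfeasibleSamplingError(f"n_train={n_train} exceeds dataset size {n}")
    if n_train < 1:
        raise InfeasibleSamplingError("n_train must be >= 1")
    cap_insert = math.ceil(n_train / ds.n_inserts)
    cap_strategy = math.ceil(n_train / ds.n_strategies)

    for attempt_seed in _child_seeds(seed, max_attempts):
        rng = np.random.default_rng(attempt_seed)
        available = list(range(n))
        insert_count: dict[int, int] = {}
        strategy_count: dict[int, int] = {}
        chosen: list[int] = []
        while len(chosen) < n_train and available:
            idx = available[int(rng.integers(len(available)))]
            rec = ds.records[idx]
            chosen.append(idx)
            insert_count[rec.insert_id] = insert_count.get(rec.insert_id, 0) + 1
            strategy_count[rec.strategy_id] = (
                strategy_count.get(rec.strategy_id, 0) + 1)
            saturated_i = insert_count[rec.insert_id] >= cap_insert
            saturated_s = strategy_count[rec.strategy_id] >= cap_strategy
            available = [
                j for j in available if j != idx
                and not (saturated_i and ds.records[j].insert_id == rec.insert_id)
                and not (saturated_s and ds.records[j].strategy_id == rec.strategy_id)]
        if len(chosen) == n_train:
            chosen_set = set(chosen)
            rest = [i for i in range(n) if i not in chosen_set]
            return ds.subset(sorted(chosen)), ds.subset(rest)
    raise InfeasibleSamplingError(
        f"could not draw {n_train} records under caps "
        f"(insert<={cap_insert}, strategy<={cap_strategy})")


# ---------------------------------------------------- Monte Carlo CV

@dataclass
class CVResult:
    """Per-fold MCC values for each candidate ensemble size k.

    ``fold_mcc`` has shape (n_folds, len(k_values)); undefined MCCs are
    stored as NaN and excluded from medians/MADs.
    """

    k_values: list[int]
    fold_mcc: np.ndarray
    fold_seeds: list[int]

    @property
    def n_folds(self) -> int:
        return self.fold_mcc.shape[0]

    def n_undefined(self) -> np.ndarray:
        return np.isnan(self.fold_mcc).sum(axis=0)

    def summary(self) -> pd.DataFrame:
        """Median and MAD of MCC per k, excluding undefined folds."""
        rows = []
        for j, k in enumerate(self.k_values):
            col = self.fold_mcc[:, j]
            col = col[~np.isnan(col)]
            if col.size:
                med, mad = median_mad(col)
            else:
                med, mad = float("nan"), float("nan")
            rows.append({"k": k, "median_mcc": med, "mad_mcc": mad,
                         "n_defined": col.size})
        return pd.DataFrame(rows)

    def tidy(self) -> pd.DataFrame:
        """One row per (fold, k)."""
        folds, ks = np.meshgrid(
            np.arange(self.n_folds), np.asarray(self.k_values), indexing="ij")
        return pd.DataFrame({
            "fold": folds.ravel(), "k": ks.ravel(),
            "mcc": self.fold_mcc.ravel()})


def _evaluate_k_range(model: EnsembleModel, fm: FeatureMatrix,
                      y: np.ndarray, k_values: Sequence[int]) -> np.ndarray:
    """MCC (NaN when undefined) of the top-k ensemble for each k.

    Incremental over k: stump votes are accumulated once per stump.
    """
    n = len(fm.frame)
    score0 = np.zeros(n)
    score1 = np.zeros(n)
    out = np.full(len(k_values), np.nan)
    k_index = {k: j for j, k in enumerate(k_values)}
    for rank, stump in enumerate(model.stumps, start=1):
        cls, prob = stump.predict_array(fm.column(stump.scale_id))
        score0 += np.where(cls == 0, prob, 0.0)
        score1 += np.where(cls == 1, prob, 0.0)
        if rank in k_index:
            pred = (score1 > score0).astype(int)
            out[k_index[rank]] = _mcc_or_nan(
                ConfusionMatrix.from_labels(y, pred))
        if rank >= max(k_values):
            break
    return out


def mc_cv(ds: Dataset, library: ScaleLibrary, n_folds: int = 100,
          train_frac: float = 0.5, k_values: Optional[Sequence[int]] = None,
          trim_n: int = 0, trim_c: int = 0, seed: int = 0,
          unknown_aa: str = "error") -> CVResult:
    """Monte Carlo cross-validation of the sEVC.

    Each fold draws ``floor(n * train_frac)`` records at random without
    replacement for training and predicts the remainder.  Stump induction
    *and* feature selection happen inside each fold.  Folds where the MCC
    is undefined are recorded as NaN.
    """
    if len(ds) < 4:
        raise EvaluationError("MC-CV needs at least 4 labeled records")
    y_all = ds.labels()
    fm = build_feature_matrix(ds, library, trim_n, trim_c, unknown_aa)
    if k_values is None:
        k_values = list(range(1, len(library) + 1))
    k_values = list(k_values)
    n = len(ds)
    n_train = int(n * train_frac)
    fold_seeds = _child_seeds(seed, n_folds)
    fold_mcc = np.full((n_folds, len(k_values)), np.nan)
    for f, fold_seed in enumerate(fold_seeds):
        rng = np.random.default_rng(fold_seed)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        fm_tr = FeatureMatrix(fm.frame.iloc[tr], trim_n, trim_c)
        fm_te = FeatureMatrix(fm.frame.iloc[te], trim_n, trim_c)
        model = train_ensemble(fm_tr, y_all[tr])
        fold_mcc[f] = _evaluate_k_range(model, fm_te, y_all[te], k_values)
    return CVResult(k_values=k_values, fold_mcc=fold_mcc,
                    fold_seeds=fold_seeds)


# ------------------------------------------------- learning experiment

def default_learning_sizes(n_pool: int) -> list[int]:
    """Training-set sizes in 5% steps of the pool, plus the full pool.

    ``floor(0.05 * i * n_pool)`` for i = 1..18, then ``n_pool`` itself as
    the final size (19 sizes in total; for a pool of 384 this gives
    19, 38, 57, ..., 345, 384).
    """
    sizes = [int(math.floor(0.05 * i * n_pool)) for i in range(1, 19)]
    sizes.append(n_pool)
    return sizes


class _GroupCounter:
    """Accumulates per-strategy classification-group counts across models."""

    def __init__(self) -> None:
        self.counts: dict[int, np.ndarray] = {}

    def add(self, strategies, y_true, y_pred) -> None:
        s = np.asarray(strategies)
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        group = np.where(
            (t == 1) & (p == 1), 0, np.where(
                (t == 0) & (p == 0), 1, np.where(
                    (t == 0) & (p == 1), 2, 3)))
        for strat in np.unique(s):
            row = self.counts.setdefault(int(strat), np.zeros(4))
            row += np.bincount(group[s == strat], minlength=4)

    def frame(self) -> pd.DataFrame:
        if not self.counts:
            raise EvaluationError("no predictions accumulated")
        idx = sorted(self.counts)
        return pd.DataFrame(
            [self.counts[i] for i in idx], index=idx, columns=list(GROUPS))


@dataclass
class LearningGrid:
    """Replicate MCCs over (training size, repetition, ensemble size k).

    Median/MAD summaries are recomputed from the stored replicate arrays.
    When group collection is enabled, per-strategy classification-group
    counts over all models are kept for train and test predictions.
    """

    sizes: list[int]
    k_values: list[int]
    reps: int
    train_mcc: np.ndarray  # (n_sizes, reps, n_k), NaN = undefined
    test_mcc: np.ndarray
    rep_seeds: list[list[int]]
    train_groups: Optional[pd.DataFrame] = None
    test_groups: Optional[pd.DataFrame] = None

    def n_models(self) -> int:
        return len(self.sizes) * self.reps * len(self.k_values)

    def _summary(self, arr: np.ndarray, subset: str) -> pd.DataFrame:
        rows = []
        for i, size in enumerate(self.sizes):
            for j, k in enumerate(self.k_values):
                cell = arr[i, :, j]
                cell = cell[~np.isnan(cell)]
                med, mad = (median_mad(cell) if cell.size
                            else (float("nan"), float("nan")))
                rows.append({"subset": subset, "n_train": size, "k": k,
                             "median_mcc": med, "mad_mcc": mad,
                             "n_defined": cell.size})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.concat([self._summary(self.train_mcc, "train"),
                          self._summary(self.test_mcc, "test")],
                         ignore_index=True)

    def tidy(self) -> pd.DataFrame:
        """One row per (subset, size, rep, k) replicate."""
        rows = []
        for subset, arr in (("train", self.train_mcc), ("test", self.test_mcc)):
            for i, size in enumerate(self.sizes):
                for r in range(self.reps):
                    for j, k in enumerate(self.k_values):
                        rows.append({"subset": subset, "n_train": size,
                                     "rep": r, "k": k, "mcc": arr[i, r, j]})
        return pd.DataFrame(rows)


def learning_experiment(pool: Dataset, test: Dataset, library: ScaleLibrary,
                        sizes: Optional[Sequence[int]] = None, reps: int = 10,
                        k_values: Optional[Sequence[int]] = None,
                        trim_n: int = 0, trim_c: int = 0, seed: int = 0,
                        unknown_aa: str = "error",
                        collect_groups: bool = False) -> LearningGrid:
    """Map sEVC performance over training size and number of classifiers.

    For every (size, repetition) a training set is drawn at random from
    ``pool`` *without* stratification, an ensemble with embedded feature
    selection is trained on it, and the top-1..k ensembles are evaluated on
    the training draw and on the fixed external ``test`` set.
    """
    y_pool = pool.labels()
    y_test = test.labels()
    fm_pool = build_feature_matrix(pool, library, trim_n, trim_c, unknown_aa)
    fm_test = build_feature_matrix(test, library, trim_n, trim_c, unknown_aa)
    if sizes is None:
        sizes = default_learning_sizes(len(pool))
    if k_values is None:
        k_values = list(range(1, len(library) + 1))
    sizes, k_values = list(sizes), list(k_values)
    if max(sizes) > len(pool):
        raise EvaluationError("training size exceeds pool size")

    strat_test = np.array([r.strategy_id for r in test])
    strat_pool = np.array([r.strategy_id for r in pool])
    counter_tr = _GroupCounter() if collect_groups else None
    counter_te = _GroupCounter() if collect_groups else None

    train_mcc = np.full((len(sizes), reps, len(k_values)), np.nan)
    test_mcc = np.full_like(train_mcc, np.nan)
    all_seeds = _child_seeds(seed, len(sizes) * reps)
    rep_seeds = [all_seeds[i * reps:(i + 1) * reps] for i in range(len(sizes))]

    for i, size in enumerate(sizes):
        for r in range(reps):
            rng = np.random.default_rng(rep_seeds[i][r])
            draw = rng.choice(len(pool), size=size, replace=False)
            fm_tr = FeatureMatrix(fm_pool.frame.iloc[draw], trim_n, trim_c)
            y_tr = y_pool[draw]
            model = train_ensemble(fm_tr, y_tr)
            train_mcc[i, r] = _evaluate_k_range(model, fm_tr, y_tr, k_values)
            test_mcc[i, r] = _evaluate_k_range(model, fm_test, y_test, k_values)
            if collect_groups:
                for k in k_values:
                    pred_tr = predict_dataset(model, fm_tr, k)["predicted"]
                    pred_te = predict_dataset(model, fm_test, k)["predicted"]
                    counter_tr.add(strat_pool[draw], y_tr, pred_tr.to_numpy())
                    counter_te.add(strat_test, y_test, pred_te.to_numpy())

    return LearningGrid(
        sizes=sizes, k_values=k_values, reps=reps,
        train_mcc=train_mcc, test_mcc=test_mcc, rep_seeds=rep_seeds,
        train_groups=counter_tr.frame() if collect_groups else None,
        test_groups=counter_te.frame() if collect_groups else None)


# ------------------------------------------- misclassification analysis

def misclassification_frequency(predictions: Iterable | pd.DataFrame
                                ) -> pd.DataFrame:
    """Per-strategy relative frequency of TP/TN/FP/FN across many models.

    ``predictions`` is either an iterable of ``(strategy_ids, y_true,
    y_pred)`` triples (one per model) or an already-accumulated counts
    DataFrame (strategies x groups, e.g. ``LearningGrid.test_groups``).
    Each strategy's occurrences are summed over all models and groups and
    the four group counts are normalized by that total, so every row sums
    to 1.  A strategy overrepresented in FP relative to FN is one whose
    solubility the models systematically overestimate.
    """
    if isinstance(predictions, pd.DataFrame):
        counts = predictions[list(GROUPS)].astype(float)
    else:
        counter = _GroupCounter()
        for strategies, y_true, y_pred in predictions:
            counter.add(strategies, y_true, y_pred)
        counts = counter.frame()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(counts.index[totals == 0])
        raise EvaluationError(f"strategies with no predictions: {bad}")
    return counts.div(totals, axis=0)


# --------------------------------------------------------- baselines

def _baseline(features: np.ndarray, y: np.ndarray, scale_id: str
              ) -> tuple[DecisionStump, ConfusionMatrix]:
    stump = fit_stump(features, y, scale_id=scale_id)
    pred, _ = stump.predict_array(features)
    return stump, ConfusionMatrix.from_labels(y, pred)


def kr_baseline(ds: Dataset) -> tuple[DecisionStump, ConfusionMatrix]:
    """One-level tree on the lysine/arginine count ratio of each sequence."""
    y = ds.labels()
    feats = np.array([kr_ratio(r.sequence) for r in ds])
    return _baseline(feats, y, "K/R")


def charge_baseline(ds: Dataset, trim_n: int = 0, trim_c: int = 0
                    ) -> tuple[DecisionStump, ConfusionMatrix]:
    """One-level tree on the net-charge feature (D,E = -1; R,K = +1)."""
    from .features import compute_feature
    y = ds.labels()
    cs = charge_scale()
    feats = np.array([compute_feature(r.sequence, cs, trim_n, trim_c)
                      for r in ds])
    return _baseline(feats, y, cs.id)
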