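"""Metrics, stratified sampling, MC-CV, learning grid, misclassification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from sevc.evaluation import (ConfusionMatrix, EvaluationError,
                             InfeasibleSamplingError, UndefinedMCCError,
                             accuracy, charge_baseline, default_learning_sizes,
                             kr_baseline, learning_experiment, mc_cv, mcc,
                             median_mad, misclassification_frequency,
                             stratified_sample)
from sevc.features import (ConstructRecord, Dataset, build_feature_matrix)
from sevc.scales import ScaleLibrary
from sevc.stump import fit_stump
from sevc.synthetic import SyntheticConfig, generate_dataset

from oracles import brute_mcc, brute_median_mad


class TestMCC:
    def test_perfect_classifier(self):
        assert mcc(ConfusionMatrix(tp=50, tn=50, fp=0, fn=0)) == 1.0

    def test_balanced_symmetric_accuracy_062(self):
        cm = ConfusionMatrix(tp=62, tn=62, fp=38, fn=38)
        assert accuracy(cm) == pytest.approx(0.62)
        assert mcc(cm) == pytest.approx(0.24)

    def test_hand_evaluated_small_matrix(self):
        cm = ConfusionMatrix(tp=3, tn=4, fp=2, fn=1)
        assert mcc(cm) == pytest.approx(10 / math.sqrt(600))

    def test_zero_denominator_factor_is_undefined(self):
        with pytest.raises(UndefinedMCCError):
            mcc(ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))  # no predicted 1

    def test_matches_stock_implementation(self, rng):
        for _ in range(30):
            y = rng.integers(0, 2, size=40)
            p = rng.integers(0, 2, size=40)
            cm = ConfusionMatrix.from_labels(y, p)
            try:
                ours = mcc(cm)
            except UndefinedMCCError:
                continue
            assert ours == pytest.approx(matthews_corrcoef(y, p))
            assert ours == pytest.approx(brute_mcc(cm.tp, cm.tn, cm.fp, cm.fn))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_balanced_symmetric_identity(self, good, bad):
        """For TP=TN and FP=FN, MCC = 2*accuracy - 1."""
        cm = ConfusionMatrix(tp=good, tn=good, fp=bad, fn=bad)
        assert mcc(cm) == pytest.approx(2 * accuracy(cm) - 1)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(1, 50))
    def test_relabeling_symmetries(self, tp, tn, fp, fn):
        """Renaming both classes preserves MCC and accuracy; inverting the
        predictions alone negates MCC."""
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        assert -1 <= mcc(cm) <= 1
        renamed = ConfusionMatrix(tp=tn, tn=tp, fp=fn, fn=fp)
        assert mcc(renamed) == pytest.approx(mcc(cm))
        assert accuracy(renamed) == pytest.approx(accuracy(cm))
        inverted = ConfusionMatrix(tp=fn, tn=fp, fp=tn, fn=tp)
        assert mcc(inverted) == pytest.approx(-mcc(cm))


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(ConfusionMatrix(50, 50, 0, 0)) == 1.0

    def test_hand_evaluation(self, rng):
        for _ in range(10):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(tn), int(fp), int(fn))
            assert accuracy(cm) == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn))

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            accuracy(ConfusionMatrix(0, 0, 0, 0))


class TestMedianMAD:
    def test_hand_case(self):
        assert median_mad([1, 2, 4, 7]) == (3.0, 1.5)

    def test_constant_vector(self):
        assert median_mad([5.0] * 9) == (5.0, 0.0)

    def test_singleton(self):
        assert median_mad([2.5]) == (2.5, 0.0)

    def test_matches_sort_based_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(size=int(rng.integers(1, 25))).tolist()
            med, mad = median_mad(vals)
            bmed, bmad = brute_median_mad(vals)
            assert med == pytest.approx(bmed)
            assert mad == pytest.approx(bmad)


class TestStratifiedSample:
    def test_insert_cap_one_when_24_of_71(self, grid_dataset):
        ds, _ = grid_dataset
        train, _ = stratified_sample(ds, 24, seed=3)
        inserts = [r.insert_id for r in train]
        assert max(np.bincount(inserts)) == 1  # ceil(24/71) = 1

    def test_strategy_cap_exactly_three_when_24_of_8(self, grid_dataset):
        ds, _ = grid_dataset
        train, _ = stratified_sample(ds, 24, seed=3)
        strategies = [r.strategy_id for r in train]
        counts = np.bincount(strategies)[1:]
        assert (counts == 3).all()  # 24/8 exact

    def test_same_seed_reproduces_subset(self, grid_dataset):
        ds, _ = grid_dataset
        a, _ = stratified_sample(ds, 96, seed=42)
        b, _ = stratified_sample(ds, 96, seed=42)
        assert a.construct_ids == b.construct_ids

    def test_partition_of_dataset(self, grid_dataset):
        ds, _ = grid_dataset
        train, rest = stratified_sample(ds, 192, seed=5)
        ids_train, ids_rest = set(train.construct_ids), set(rest.construct_ids)
        assert not ids_train & ids_rest
        assert ids_train | ids_rest == set(ds.construct_ids)

    def test_caps_hold_over_seeds(self, grid_dataset):
        ds, _ = grid_dataset
        for seed in range(10):
            for n in (24, 96, 384):
                train, _ = stratified_sample(ds, n, seed=seed)
                ins = np.bincount([r.insert_id for r in train])
                strat = np.bincount([r.strategy_id for r in train])
                assert ins.max() <= math.ceil(n / ds.n_inserts)
                assert strat.max() <= math.ceil(n / ds.n_strategies)

    def test_oversized_request_rejected(self, grid_dataset):
        ds, _ = grid_dataset
        with pytest.raises(InfeasibleSamplingError):
            stratified_sample(ds, len(ds) + 1, seed=0)


def _random_tiny_dataset(rng, n=10, seq_len=12):
    from sevc.scales import AMINO_ACIDS
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=seq_len))
        records.append(ConstructRecord(f"r{i}", i + 1, 1, seq,
                                       int(rng.integers(0, 2))))
    return Dataset(records, n_inserts=n, n_strategies=1)


class TestMCCV:
    def test_fold_contract(self, library, rng):
        ds = _random_tiny_dataset(rng, n=10)
        res = mc_cv(ds, library, n_folds=3, k_values=[1, 2], seed=7)
        assert res.fold_mcc.shape == (3, 2)
        assert res.n_folds == 3
        assert len(res.fold_seeds) == 3

    def test_separable_limit_has_median_mcc_one(self, grid_dataset, library):
        ds, _ = grid_dataset
        sub = ds.subset(range(0, 568, 5))
        res = mc_cv(sub, library, n_folds=5, k_values=[1],
                    trim_n=73, trim_c=71, seed=1)
        assert res.summary()["median_mcc"].iloc[0] == pytest.approx(1.0)

    def test_bit_reproducible(self, library, rng):
        ds = _random_tiny_dataset(rng, n=12)
        a = mc_cv(ds, library, n_folds=4, k_values=[1, 3], seed=9)
        b = mc_cv(ds, library, n_folds=4, k_values=[1, 3], seed=9)
        np.testing.assert_array_equal(a.fold_mcc, b.fold_mcc)

    def test_matches_step_by_step_replay(self, library, rng):
        """Scripted replay of the documented fold scheme, via low-level ops."""
        from sevc.evaluation import _mcc_or_nan
        ds = _random_tiny_dataset(rng, n=10)
        lib3 = ScaleLibrary(library.scales[:3])
        k_values = [1, 3]
        res = mc_cv(ds, lib3, n_folds=3, k_values=k_values, seed=21)

        y = ds.labels()
        fm = build_feature_matrix(ds, lib3)
        fold_seeds = np.random.default_rng(21).integers(
            0, 2 ** 31 - 1, size=3)
        assert [int(s) for s in fold_seeds] == res.fold_seeds
        for f, fs in enumerate(fold_seeds):
            perm = np.random.default_rng(int(fs)).permutation(10)
            tr, te = perm[:5], perm[5:]
            stumps = [fit_stump(fm.frame[sid].to_numpy()[tr], y[tr], sid)
                      for sid in lib3.ids]
            stumps.sort(key=lambda s: -s.training_accuracy)  # stable
            for j, k in enumerate(k_values):
                score = np.zeros((len(te), 2))
                for s in stumps[:k]:
                    for row, idx in enumerate(te):
                        cls, prob = s.predict(fm.frame[s.scale_id].iloc[idx])
                        score[row, cls] += prob
                pred = (score[:, 1] > score[:, 0]).astype(int)
                expected = _mcc_or_nan(ConfusionMatrix.from_labels(y[te], pred))
                got = res.fold_mcc[f, j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)


class TestLearningExperiment:
    def test_default_sizes_for_384(self):
        sizes = default_learning_sizes(384)
        assert len(sizes) == 19
        assert sizes[0] == 19 and sizes[-1] == 384
        assert 57 in sizes and 249 in sizes
        assert sizes == sorted(sizes)

    def test_zero_noise_median_test_mcc_is_one_at_k1(self, grid_dataset,
                                                     library):
        ds, _ = grid_dataset
        pool, test = stratified_sample(ds, 384, seed=2)
        grid = learning_experiment(pool, test, library, sizes=[96, 192],
                                   reps=3, k_values=[1], trim_n=73,
                                   trim_c=71, seed=2)
        summary = grid.summary()
        test_rows = summary[summary.subset == "test"]
        assert np.allclose(test_rows["median_mcc"], 1.0)

    def test_summary_recomputable_from_replicates(self, grid_dataset, library):
        ds, _ = grid_dataset
        pool, test = stratified_sample(ds, 200, seed=4)
        grid = learning_experiment(pool, test, library, sizes=[40, 80],
                                   reps=3, k_values=[1, 2, 5], trim_n=73,
                                   trim_c=71, seed=4)
        tidy = grid.tidy()
        for _, row in grid.summary().iterrows():
            cell = tidy[(tidy.subset == row.subset)
                        & (tidy.n_train == row.n_train)
                        & (tidy.k == row.k)]["mcc"].dropna()
            med, mad = brute_median_mad(cell.tolist())
            assert row.median_mcc == pytest.approx(med)
            assert row.mad_mcc == pytest.approx(mad)

    def test_bit_reproducible(self, grid_dataset, library):
        ds, _ = grid_dataset
        pool, test = stratified_sample(ds, 100, seed=6)
        kwargs = dict(sizes=[30, 60], reps=2, k_values=[1, 2],
                      trim_n=73, trim_c=71, seed=13)
        a = learning_experiment(pool, test, library, **kwargs)
        b = learning_experiment(pool, test, library, **kwargs)
        np.testing.assert_array_equal(a.test_mcc, b.test_mcc)
        np.testing.assert_array_equal(a.train_mcc, b.train_mcc)


class TestMisclassificationFrequency:
    def test_single_model_all_true_positives(self):
        freq = misclassification_frequency(
            [(np.ones(5, dtype=int), np.ones(5, dtype=int),
              np.ones(5, dtype=int))])
        assert freq.loc[1, "TP"] == 1.0
        assert freq.loc[1, ["TN", "FP", "FN"]].sum() == 0.0

    def test_rows_sum_to_one(self, rng):
        models = []
        for _ in range(5):
            strat = rng.integers(1, 9, size=50)
            models.append((strat, rng.integers(0, 2, size=50),
                           rng.integers(0, 2, size=50)))
        freq = misclassification_frequency(models)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)

    def test_adversarial_strategy_dominates_errors(self, library):
        """A strategy with flipped labels collects the most FP+FN mass."""
        cfg = SyntheticConfig(seed=5, flip_strategy=8, flip_prob=1.0)
        ds, truth = generate_dataset(cfg)
        assert len(truth.adversarial_flipped) == 71
        pool, test = stratified_sample(ds, 384, seed=5)
        grid = learning_experiment(pool, test, library, sizes=[192, 384],
                                   reps=2, k_values=[1, 3], trim_n=73,
                                   trim_c=71, seed=5, collect_groups=True)
        freq = misclassification_frequency(grid.test_groups)
        errors = freq["FP"] + freq["FN"]
        assert errors.idxmax() == 8
        assert (errors.drop(8) < errors.loc[8]).all()


def _kr_dataset():
    records = []
    for k in range(1, 11):  # K/R = k/10
        seq = "K" * k + "R" * 10 + "A" * 5
        records.append(ConstructRecord(f"kr{k}", k, 1, seq,
                                       label=1 if k / 10 < 0.5 else 0))
    return Dataset(records, n_inserts=10, n_strategies=1)


class TestBaselines:
    def test_kr_baseline_recovers_separating_threshold(self):
        ds = _kr_dataset()
        stump, cm = kr_baseline(ds)
        assert 0.4 < stump.threshold < 0.5
        assert mcc(cm) == pytest.approx(1.0)

    def test_kr_baseline_low_ratio_predicts_soluble(self):
        stump, _ = kr_baseline(_kr_dataset())
        assert stump.left_class == 1  # below the cut point -> soluble

    def test_kr_baseline_accuracy_matches_recomputation(self):
        ds = _kr_dataset()
        stump, cm = kr_baseline(ds)
        from sevc.features import kr_ratio
        pred = [stump.predict(kr_ratio(r.sequence))[0] for r in ds]
        correct = sum(p == r.label for p, r in zip(pred, ds))
        assert accuracy(cm) == pytest.approx(correct / len(ds))

    def test_charge_baseline_separable_by_net_charge(self):
        records = []
        for i, n_pos in enumerate(range(1, 9)):
            seq = "R" * n_pos + "D" * 4 + "G" * 5
            records.append(ConstructRecord(f"q{i}", i + 1, 1, seq,
                                           label=1 if n_pos - 4 < 0 else 0))
        ds = Dataset(records, n_inserts=8, n_strategies=1)
        stump, cm = charge_baseline(ds)
        assert mcc(cm) == pytest.approx(1.0)
        assert accuracy(cm) == pytest.approx(1.0)

    def test_charge_baseline_hand_confusion_matrix(self, rng):
        records = []
        for i in range(12):
            seq = ("R" * int(rng.integers(0, 5)) + "K" * int(rng.integers(0, 5))
                   + "D" * int(rng.integers(0, 5)) + "G" * 6)
            records.append(ConstructRecord(f"m{i}", i + 1, 1, seq,
                                           label=int(rng.integers(0, 2))))
        ds = Dataset(records, n_inserts=12, n_strategies=1)
        stump, cm = charge_baseline(ds)
        from sevc.features import compute_feature
        from sevc.scales import charge_scale
        pred = [stump.predict(compute_feature(r.sequence, charge_scale()))[0]
                for r in ds]
        manual = ConfusionMatrix.from_labels([r.label for r in ds], pred)
        assert manual == cm
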