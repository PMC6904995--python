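"""Balanced-undersampling KNN protocol: vote, CV, selection, hold-out."""

import numpy as np
import pytest

import ionbind as ib
from ionbind.features import FeatureExtractor
from ionbind.protocol import optimal_k_from_curve, split_chains


def brute_force_knn(train_x, train_y, test_x, k):
    """Independent exhaustive-search oracle with the same tie rule."""
    preds = []
    for t in test_x:
        dist = [(float(np.sum((t - x) ** 2)), i) for i, x in enumerate(train_x)]
        dist.sort()  # distance first, then training-row index
        votes = sum(train_y[i] for _, i in dist[:k])
        preds.append(votes * 2 > k)
    return np.array(preds)


def planted_dataset(seed=11, n_chains=30, strength=0.9, **kw):
    cfg = ib.SyntheticConfig(n_chains=n_chains, motif_strength=strength,
                             seed=seed, **kw)
    records, _ = ib.generate_synthetic_dataset(cfg)
    return records, cfg.ligand_code


class TestUndersampling:
    def test_balance_contract(self, small_dataset):
        _, records, _ = small_dataset
        segs = ib.segments_from_records(records, "SO4", 9)
        n_pos = sum(s.positive for s in segs)
        balanced = ib.undersample_negatives(segs, seed=0)
        assert len(balanced) == 2 * n_pos
        assert sum(s.positive for s in balanced) == n_pos
        # every positive kept
        assert {id(s) for s in segs if s.positive} <= {id(s) for s in balanced}

    def test_deterministic_per_seed_and_seed_sensitive(self, small_dataset):
        _, records, _ = small_dataset
        segs = ib.segments_from_records(records, "SO4", 9)
        a = ib.undersample_negatives(segs, seed=1)
        b = ib.undersample_negatives(segs, seed=1)
        c = ib.undersample_negatives(segs, seed=2)
        assert [id(s) for s in a] == [id(s) for s in b]
        assert [id(s) for s in a] != [id(s) for s in c]

    def test_more_positives_than_negatives_rejected(self):
        records, lig = planted_dataset(n_chains=4)
        segs = [s for s in ib.segments_from_records(records, lig, 5)
                if s.positive]
        with pytest.raises(ValueError, match="cannot balance"):
            ib.undersample_negatives(segs, seed=0)


class TestKnnPredict:
    def test_hand_worked_neighbourhood(self):
        train_x = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        train_y = np.array([False, True, True])
        assert ib.knn_predict(train_x, train_y, [[0.9, 0.1]], k=3)[0]

    def test_k1_returns_label_of_coincident_point(self):
        train_x = np.array([[0.0, 0.0], [5.0, 5.0]])
        train_y = np.array([True, False])
        assert ib.knn_predict(train_x, train_y, [[0.0, 0.0]], k=1)[0]

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_exhaustive_oracle_on_random_points(self, k):
        rng = np.random.default_rng(7)
        train_x = rng.normal(size=(200, 5))
        train_y = rng.integers(0, 2, 200).astype(bool)
        test_x = rng.normal(size=(40, 5))
        got = ib.knn_predict(train_x, train_y, test_x, k)
        assert np.array_equal(got, brute_force_knn(train_x, train_y, test_x, k))

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_oracle_under_engineered_distance_ties(self, k):
        rng = np.random.default_rng(8)
        # integer grid points force exact repeated distances
        train_x = rng.integers(0, 3, size=(200, 5)).astype(float)
        train_y = rng.integers(0, 2, 200).astype(bool)
        test_x = rng.integers(0, 3, size=(40, 5)).astype(float)
        got = ib.knn_predict(train_x, train_y, test_x, k)
        assert np.array_equal(got, brute_force_knn(train_x, train_y, test_x, k))

    def test_even_or_oversized_k_rejected(self):
        x = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1], dtype=bool)
        with pytest.raises(ValueError):
            ib.knn_predict(x, y, x, k=2)
        with pytest.raises(ValueError):
            ib.knn_predict(x, y, x, k=5)


class TestOptimalKArithmetic:
    def test_worked_average_of_ten_resample_optima(self):
        optima = [33, 27, 29, 31, 31, 33, 35, 35, 37, 39]
        assert ib.average_optimal_k(optima) == 33

    def test_unanimous_resamples(self):
        assert ib.average_optimal_k([15] * 10) == 15

    def test_even_mean_rounds_to_smaller_odd(self):
        assert ib.average_optimal_k([31, 33]) == 31  # mean 32.0

    def test_fractional_mean_rounds_to_nearest_odd(self):
        assert ib.average_optimal_k([33, 36]) == 35  # mean 34.5 -> nearer 35

    def test_curve_argmax_ties_take_smaller_k(self):
        assert optimal_k_from_curve([1, 3, 5], [0.4, 0.6, 0.6]) == 3


class TestCrossValidation:
    def test_folds_are_stratified_and_counted(self):
        records, lig = planted_dataset()
        balanced = ib.undersample_negatives(
            ib.segments_from_records(records, lig, 9), seed=0
        )
        res = ib.cross_validate(balanced, "C", 9, k=5, seed=0)
        assert len(res.folds) == 5
        n = len(balanced)
        for fold in res.folds:
            total = fold.tp + fold.fp + fold.tn + fold.fn
            assert abs(total - n / 5) < 1
            # positive fraction of the fold within one segment of one half
            assert abs((fold.tp + fold.fn) - total / 2) <= 1

    def test_pooled_counts_sum_over_folds(self):
        records, lig = planted_dataset(seed=5)
        balanced = ib.undersample_negatives(
            ib.segments_from_records(records, lig, 9), seed=1
        )
        res = ib.cross_validate(balanced, "R", 9, k=7, seed=3)
        for attr in ("tp", "fp", "tn", "fn"):
            assert getattr(res.pooled, attr) == sum(getattr(f, attr)
                                                    for f in res.folds)
        recomputed = ib.metrics(res.pooled.tp, res.pooled.fp,
                                res.pooled.tn, res.pooled.fn)
        assert recomputed.mcc == res.pooled.mcc

    def test_strong_signal_is_nearly_separable(self):
        records, lig = planted_dataset(strength=1.0, seed=2)
        balanced = ib.undersample_negatives(
            ib.segments_from_records(records, lig, 9), seed=0
        )
        res = ib.cross_validate(balanced, "R", 9, k=5, seed=0)
        assert res.pooled.mcc > 0.9

    def test_tiny_class_rejected(self):
        records, lig = planted_dataset(n_chains=4)
        segs = ib.segments_from_records(records, lig, 5)
        balanced = ib.undersample_negatives(segs, 0)[:6]  # too few per class
        with pytest.raises(ValueError):
            ib.cross_validate(balanced, "C", 5, k=1, seed=0, n_folds=5)

    def test_signal_strength_orders_mcc(self):
        """Paired over seeds, strong planted signal beats weak signal."""
        wins = 0
        for seed in range(5):
            mccs = []
            for strength in (0.1, 0.9):
                records, lig = planted_dataset(seed=seed, strength=strength,
                                               n_chains=15)
                balanced = ib.undersample_negatives(
                    ib.segments_from_records(records, lig, 9), seed=seed
                )
                mccs.append(ib.cross_validate(balanced, "R", 9, 7, seed).pooled.mcc)
            wins += mccs[1] > mccs[0]
        assert wins == 5


class TestNoLeakage:
    def test_fold_state_ignores_test_segments(self):
        records, lig = planted_dataset(seed=9)
        balanced = ib.undersample_negatives(
            ib.segments_from_records(records, lig, 9), seed=0
        )
        train, test = balanced[:300], balanced[300:]
        baseline = FeatureExtractor("R", 9).fit(train).state_hash()
        # replace the test portion entirely; the fitted state must not move
        mutated_test = [
            ib.Segment(s.chain_id, s.center_index, "A" * 9, not s.positive,
                       {t: w[::-1] for t, w in s.track_windows.items()})
            for s in test
        ]
        assert FeatureExtractor("R", 9).fit(train).state_hash() == baseline
        del mutated_test
        # and a different training set must change it
        assert FeatureExtractor("R", 9).fit(train[:-5]).state_hash() != baseline


class TestIndependentTest:
    def test_split_contract(self):
        records, _ = planted_dataset(n_chains=100, seed=3)
        train, test = split_chains(records, split_seed=4)
        assert len(train) == 80 and len(test) == 20
        assert not {r.chain_id for r in train} & {r.chain_id for r in test}
        train2, test2 = split_chains(records, split_seed=4)
        assert [r.chain_id for r in train2] == [r.chain_id for r in train]

    def test_holdout_metrics_on_imbalanced_test_side(self):
        records, lig = planted_dataset(n_chains=40, seed=6)
        config = ib.KnnConfig(n_resamples=4, seed=0)
        res = ib.independent_test(records, lig, "R", 9, k=7, config=config,
                                  split_seed=1)
        total = sum((res.result.tp, res.result.fp, res.result.tn, res.result.fn))
        assert total == res.test_summary["positives"] + res.test_summary["negatives"]
        assert res.test_summary["negatives"] > 5 * res.test_summary["positives"]
        assert res.result.sp > 80.0 and res.result.sn > 50.0

    def test_no_positive_test_side_rejected(self):
        records, lig = planted_dataset(n_chains=10, seed=1)
        # strip annotations from every chain so the held-out side is empty
        for rec in records:
            rec.binding[lig][:] = False
        with pytest.raises(ValueError, match="no positive"):
            ib.independent_test(records, lig, "R", 9, 5,
                                ib.KnnConfig(n_resamples=2), split_seed=0)


class TestProtocolBookkeeping:
    def test_mean_metrics_recomputable_from_archived_results(self):
        records, lig = planted_dataset(seed=8, n_chains=15)
        segs = ib.segments_from_records(records, lig, 9)
        config = ib.KnnConfig(n_resamples=3, seed=5)
        res = ib.run_protocol(segs, "R", 9, k=5, config=config)
        assert len(res.resamples) == 3
        mean_mcc = np.mean([r.pooled.mcc for r in res.resamples])
        assert res.mean_metrics["MCC"] == pytest.approx(mean_mcc)
        fold_means = res.resamples[0].fold_mean
        assert fold_means["MCC"] == pytest.approx(
            np.mean([f.mcc for f in res.resamples[0].folds])
        )

    def test_k_selection_reports_resample_optima(self):
        records, lig = planted_dataset(seed=10, n_chains=12)
        segs = ib.segments_from_records(records, lig, 9)
        config = ib.KnnConfig(k_grid=(1, 3, 5, 7), n_resamples=3, seed=2)
        sel = ib.select_optimal_k(segs, "R", 9, config)
        assert len(sel.per_resample) == 3
        assert sel.k == ib.average_optimal_k(sel.per_resample)
        assert all(k in (1, 3, 5, 7) for k in sel.per_resample)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ib.KnnConfig(k_grid=(1, 2, 3))
        with pytest.raises(ValueError):
            ib.KnnConfig(k_grid=(5, 3, 1))
        with pytest.raises(ValueError):
            ib.KnnConfig(k=4)
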