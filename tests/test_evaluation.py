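import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdalp
from mdalp import (
    CVPlan,
    MdalpError,
    MetricsReport,
    compute_metrics,
    grid_search,
    make_folds,
    rank_auc,
    run_cv,
)
from mdalp.model import MDAModel, PipelineConfig


def brute_force_auc(pos, neg):
    """Count positive>negative pairs (ties half), normalized."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def test_perfect_ranking(self):
        assert rank_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_hand_case_three_quarters(self):
        assert rank_auc([0.9, 0.4], [0.6, 0.1]) == pytest.approx(0.75)

    @given(
        pos=st.lists(st.integers(0, 9), min_size=1, max_size=25),
        neg=st.lists(st.integers(0, 9), min_size=1, max_size=25),
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_pairwise_counting(self, pos, neg):
        # integer scores force ties, exercising tied-rank averaging
        assert rank_auc(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.random(30)
        neg = rng.random(50)
        y = np.r_[np.ones(30), np.zeros(50)]
        assert rank_auc(pos, neg) == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
        )

    def test_empty_negatives_undefined(self):
        with pytest.raises(MdalpError):
            rank_auc([1.0], [])


class TestComputeMetrics:
    def test_hand_contingency(self):
        # build a score matrix realizing TP=3, FN=1, FP=2, TN=4 under the
        # prevalence-matching threshold (top-4 of 10 test pairs)
        scores = np.array([[0.9, 0.8, 0.7, 0.65, 0.6, 0.55, 0.3, 0.2, 0.1, 0.05]])
        pos = np.array([[0, 0], [0, 1], [0, 2], [0, 6]])  # one positive ranks low
        neg = np.array([[0, j] for j in (3, 4, 5, 7, 8, 9)])
        rep = compute_metrics(scores, pos, neg)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (3, 1, 1, 5)
        assert rep.sensitivity == pytest.approx(0.75)

    def test_metric_formulas_from_counts(self):
        rep = MetricsReport(
            tp=3, fp=2, tn=4, fn=1,
            sensitivity=0.75, specificity=4 / 6, accuracy=0.7, auc=0.5,
        )
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.666667, abs=1e-6)
        assert rep.accuracy == pytest.approx(0.7)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(MdalpError):
            MetricsReport(tp=3, fp=2, tn=4, fn=1, sensitivity=0.9,
                          specificity=4 / 6, accuracy=0.7, auc=0.5)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(MdalpError):
            compute_metrics(np.ones((2, 2)), np.array([[0, 0]]),
                            np.array([[0, 0]]))

    def test_specificity_tracks_accuracy_when_negatives_dominate(self, rng):
        scores = rng.random((40, 30))
        pos = np.array([[i, 0] for i in range(10)])
        neg = np.array(
            [[i, j] for i in range(40) for j in range(1, 30)]
        )  # 1160 negatives >= 100x positives
        rep = compute_metrics(scores, pos, neg)
        assert abs(rep.specificity - rep.accuracy) < 0.01


class TestMakeFolds:
    @pytest.fixture()
    def Y(self, small_data):
        return small_data[0]

    def test_cv1_partitions_rows(self, Y):
        plan = CVPlan("CV1", n_folds=5, seed=1)
        folds = make_folds(Y, plan)
        masked = np.concatenate([f.masked for f in folds])
        assert sorted(masked) == list(range(Y.n_microbes))
        assert {len(f.masked) for f in folds} == {Y.n_microbes // 5}

    def test_cv2_partitions_columns(self, Y):
        plan = CVPlan("CV2", n_folds=5, seed=1)
        folds = make_folds(Y, plan)
        masked = np.concatenate([f.masked for f in folds])
        assert sorted(masked) == list(range(Y.n_diseases))

    def test_cv3_partitions_positives(self, Y):
        plan = CVPlan("CV3", n_folds=5, seed=1)
        folds = make_folds(Y, plan)
        total = sum(f.test_positives.shape[0] for f in folds)
        assert total == Y.n_positives
        seen = set()
        for f in folds:
            for pair in map(tuple, f.test_positives):
                assert pair not in seen
                seen.add(pair)

    @pytest.mark.parametrize("scheme", ["CV1", "CV2", "CV3"])
    def test_same_seed_reproduces_folds(self, Y, scheme):
        plan = CVPlan(scheme, n_folds=5, seed=7)
        a = make_folds(Y, plan)
        b = make_folds(Y, plan)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.train_values, fb.train_values)
            np.testing.assert_array_equal(fa.test_positives, fb.test_positives)

    @pytest.mark.parametrize("scheme", ["CV1", "CV2", "CV3"])
    def test_no_leakage_masked_entries_zero_in_training(self, Y, scheme):
        for fold in make_folds(Y, CVPlan(scheme, n_folds=5, seed=2)):
            tp = fold.test_positives
            assert not fold.train_values[tp[:, 0], tp[:, 1]].any()

    def test_too_few_columns_rejected(self):
        Y = mdalp.generate(
            mdalp.SyntheticConfig(n_microbes=10, m_diseases=3, n_clusters=2,
                                  symptom_dim=4, seed=0)
        )[0]
        with pytest.raises(MdalpError):
            make_folds(Y, CVPlan("CV2", n_folds=5))


class TestRunCv:
    def test_fit_count_bookkeeping(self, small_data):
        Y, sym, _ = small_data
        plan = CVPlan("CV3", n_folds=3, n_trials=2, seed=0)
        before = MDAModel.n_fits_total
        result = run_cv(Y, plan, symptoms=sym)
        assert result.n_fits == 2 * 3
        assert MDAModel.n_fits_total - before == 6
        assert len(result.table) == 6

    def test_signal_beats_chance_on_planted_clusters(self, small_data):
        Y, sym, _ = small_data
        plan = CVPlan("CV3", n_folds=5, n_trials=3, seed=0)
        result = run_cv(Y, plan, symptoms=sym)
        se = result.std_auc / np.sqrt(len(result.table))
        assert result.mean_auc > 0.5 + 5 * se

    def test_null_calibration_on_shuffled_labels(self, small_data):
        Y, sym, _ = small_data
        null = mdalp.simulate.shuffle_associations(Y, seed=11)
        plan = CVPlan("CV3", n_folds=5, n_trials=3, seed=0)
        result = run_cv(null, plan, symptoms=sym)
        assert abs(result.mean_auc - 0.5) < 0.06

    def test_summary_mentions_scheme_and_auc(self, small_data):
        Y, sym, _ = small_data
        result = run_cv(Y, CVPlan("CV3", n_folds=3, n_trials=1, seed=0),
                        symptoms=sym)
        text = result.summary()
        assert "CV3" in text and "AUC" in text


class TestGridSearch:
    def test_single_point_grid_returns_that_config(self, small_data):
        Y, sym, _ = small_data
        plan = CVPlan("CV3", n_folds=3, n_trials=1, seed=0)
        best, table = grid_search(Y, {"beta": [0.3]}, plan, symptoms=sym)
        assert best.propagation.beta == 0.3
        assert len(table) == 1

    def test_two_by_two_grid_has_four_rows(self, small_data):
        Y, sym, _ = small_data
        plan = CVPlan("CV3", n_folds=3, n_trials=1, seed=0)
        best, table = grid_search(
            Y, {"beta": [0.1, 0.5], "gamma": [0.0, 0.7]}, plan, symptoms=sym
        )
        assert len(table) == 4
        assert set(table.columns) >= {"beta", "gamma", "mean_auc"}

    def test_near_singular_beta_still_finite(self, small_data):
        Y, sym, _ = small_data
        plan = CVPlan("CV3", n_folds=3, n_trials=1, seed=0)
        best, table = grid_search(Y, {"beta": [0.1, 0.9999]}, plan,
                                  symptoms=sym)
        assert np.isfinite(table["mean_auc"]).all()

    def test_unknown_parameter_rejected(self, small_data):
        Y, sym, _ = small_data
        with pytest.raises(MdalpError):
            grid_search(Y, {"bogus": [1]}, CVPlan("CV3"))
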