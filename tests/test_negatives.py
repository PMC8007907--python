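import numpy as np
import pytest

from mdalp import (
    AssociationMatrix,
    EntityIndex,
    MdalpError,
    NegativeSelectionConfig,
    SimilarityMatrix,
    build_heterogeneous_network,
    gap_similarity,
    rwr_scores,
    select_negatives,
)
import mdalp
from mdalp.model import MDAModel
from mdalp.propagation import PropagationConfig


def assoc_from(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return AssociationMatrix(
        EntityIndex("microbe", tuple(f"m{i}" for i in range(n))),
        EntityIndex("disease", tuple(f"d{j}" for j in range(m))),
        values,
    )


def sims_for(Y):
    S_M = gap_similarity(Y.values, 1.0, index=Y.microbes, role="microbe_gap")
    S_D = gap_similarity(Y.values.T, 1.0, index=Y.diseases, role="disease_gap")
    return S_M, S_D


class TestHeterogeneousNetwork:
    def test_single_pair_network(self):
        Y = assoc_from([[1.0]])
        S_M = SimilarityMatrix(Y.microbes, np.array([[1.0]]), "microbe_gap")
        S_D = SimilarityMatrix(Y.diseases, np.array([[1.0]]), "disease_gap")
        T = build_heterogeneous_network(Y, S_M, S_D)
        np.testing.assert_array_equal(T, [[0, 1], [1, 0]])

    def test_columns_stochastic_or_zero(self, rng):
        Y = assoc_from((rng.random((6, 4)) < 0.4).astype(float))
        S_M, S_D = sims_for(Y)
        T = build_heterogeneous_network(Y, S_M, S_D)
        sums = T.sum(axis=0)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_matches_scalar_loop_oracle(self, rng):
        Y = assoc_from((rng.random((5, 4)) < 0.5).astype(float))
        S_M, S_D = sims_for(Y)
        T = build_heterogeneous_network(Y, S_M, S_D)
        n, m = 5, 4
        A = np.zeros((n + m, n + m))
        for i in range(n):
            for j in range(n):
                if i != j:
                    A[i, j] = S_M.values[i, j]
        for i in range(m):
            for j in range(m):
                if i != j:
                    A[n + i, n + j] = S_D.values[i, j]
        for i in range(n):
            for j in range(m):
                A[i, n + j] = Y.values[i, j]
                A[n + j, i] = Y.values[i, j]
        expected = np.zeros_like(A)
        for c in range(n + m):
            s = A[:, c].sum()
            if s > 0:
                expected[:, c] = A[:, c] / s
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        Y = assoc_from([[1.0, 0.0]])
        S_M = SimilarityMatrix(Y.microbes, np.array([[1.0]]), "microbe_gap")
        S_bad = SimilarityMatrix(
            EntityIndex("disease", ("x",)), np.array([[1.0]]), "disease_gap"
        )
        with pytest.raises(MdalpError):
            build_heterogeneous_network(Y, S_M, S_bad)


class TestRwr:
    def test_two_node_fixed_point_by_hand(self):
        # p1 = r + (1-r) p2, p2 = (1-r) p1, r=0.5 -> p = (2/3, 1/3)
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = rwr_scores(T, [0], NegativeSelectionConfig(restart_prob=0.5))
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-8)

    def test_restart_dominates_at_high_r(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = rwr_scores(T, [0], NegativeSelectionConfig(restart_prob=0.999))
        np.testing.assert_allclose(p, [1.0, 0.0], atol=2e-3)

    def test_power_iteration_matches_linear_solve(self, rng):
        A = rng.random((9, 9))
        T = A / A.sum(axis=0, keepdims=True)
        cfg = NegativeSelectionConfig(restart_prob=0.5)
        seeds = [0, 3]
        p = rwr_scores(T, seeds, cfg)
        e = np.zeros(9)
        e[seeds] = 0.5
        direct = 0.5 * np.linalg.solve(np.eye(9) - 0.5 * T, e)
        np.testing.assert_allclose(p, direct, atol=1e-8)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_empty_seed_set_rejected(self):
        with pytest.raises(MdalpError):
            rwr_scores(np.eye(2), [])

    def test_nonconvergence_raises(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        cfg = NegativeSelectionConfig(restart_prob=0.5, max_iter=2,
                                      rwr_tolerance=1e-15)
        with pytest.raises(mdalp.ConvergenceError):
            rwr_scores(T, [0], cfg)


class TestSelectNegatives:
    def test_only_unlabeled_candidate_returned(self):
        Y = assoc_from([[1.0, 1.0], [1.0, 0.0]])
        S_M, S_D = sims_for(Y)
        negs = select_negatives(Y, S_M, S_D,
                                NegativeSelectionConfig(n_negatives=1))
        np.testing.assert_array_equal(negs.pairs, [[1, 1]])

    def test_negatives_never_include_positives(self, small_data):
        Y, _, _ = small_data
        S_M, S_D = sims_for(Y)
        negs = select_negatives(Y, S_M, S_D)
        assert len(negs) == Y.n_positives
        assert np.all(Y.values[negs.pairs[:, 0], negs.pairs[:, 1]] == 0.0)
        assert len({tuple(p) for p in negs.pairs}) == len(negs)

    def test_selection_deterministic(self, small_data):
        Y, _, _ = small_data
        S_M, S_D = sims_for(Y)
        a = select_negatives(Y, S_M, S_D)
        b = select_negatives(Y, S_M, S_D)
        np.testing.assert_array_equal(a.pairs, b.pairs)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_clamp_when_too_many_requested(self, caplog):
        Y = assoc_from([[1.0, 1.0], [1.0, 0.0]])
        S_M, S_D = sims_for(Y)
        with caplog.at_level("WARNING"):
            negs = select_negatives(
                Y, S_M, S_D, NegativeSelectionConfig(n_negatives=50)
            )
        assert len(negs) == 1
        assert "clamping" in caplog.text

    def test_scores_sorted_ascending(self, small_data):
        Y, _, _ = small_data
        S_M, S_D = sims_for(Y)
        negs = select_negatives(Y, S_M, S_D)
        assert np.all(np.diff(negs.scores) >= 0)


class TestSeparationOnSyntheticData:
    def test_masked_positives_outscore_selected_negatives(self):
        """RWR mass on held-out true positives exceeds that on selected
        negatives, averaged over seeds: negative selection avoids likely
        missing links."""
        diffs = []
        for seed in range(10):
            cfg = mdalp.SyntheticConfig(
                n_microbes=40, m_diseases=12, n_clusters=3, symptom_dim=12,
                seed=100 + seed,
            )
            Y, _, _ = mdalp.generate(cfg)
            rng = np.random.default_rng(seed)
            pos = Y.positive_pairs()
            held = pos[rng.choice(len(pos), size=len(pos) // 5, replace=False)]
            train_vals = Y.values.copy()
            train_vals[held[:, 0], held[:, 1]] = 0.0
            train = Y.with_values(train_vals)
            S_M, S_D = sims_for(train)
            negs = select_negatives(train, S_M, S_D)
            # recompute RWR scores for every unlabeled pair of the train matrix
            from mdalp.negatives import build_heterogeneous_network, rwr_scores
            T = build_heterogeneous_network(train, S_M, S_D)
            n = train.n_microbes
            score = np.zeros(train.values.shape)
            for j in range(train.n_diseases):
                seeds = np.concatenate(
                    [np.flatnonzero(train.values[:, j] == 1.0), [n + j]]
                )
                score[:, j] = rwr_scores(T, seeds)[:n]
            held_mean = score[held[:, 0], held[:, 1]].mean()
            neg_mean = score[negs.pairs[:, 0], negs.pairs[:, 1]].mean()
            diffs.append(held_mean - neg_mean)
        assert np.mean(diffs) > 0

    def test_rwr_auc_separates_masked_positives_from_negatives(self):
        cfg = mdalp.SyntheticConfig(
            n_microbes=40, m_diseases=12, n_clusters=3, symptom_dim=12, seed=5
        )
        Y, _, _ = mdalp.generate(cfg)
        rng = np.random.default_rng(5)
        pos = Y.positive_pairs()
        held = pos[rng.choice(len(pos), size=len(pos) // 5, replace=False)]
        train_vals = Y.values.copy()
        train_vals[held[:, 0], held[:, 1]] = 0.0
        train = Y.with_values(train_vals)
        S_M, S_D = sims_for(train)
        negs = select_negatives(train, S_M, S_D)
        T = build_heterogeneous_network(train, S_M, S_D)
        n = train.n_microbes
        score = np.zeros(train.values.shape)
        for j in range(train.n_diseases):
            seeds = np.concatenate(
                [np.flatnonzero(train.values[:, j] == 1.0), [n + j]]
            )
            score[:, j] = rwr_scores(T, seeds)[:n]
        auc = mdalp.rank_auc(
            score[held[:, 0], held[:, 1]],
            score[negs.pairs[:, 0], negs.pairs[:, 1]],
        )
        assert auc > 0.5
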