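"""Filter scores (entropy, IG, gain ratio, correlation, ReliefF) and the
ranking operation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igselect import (
    ExpressionDataset,
    SyntheticSpec,
    conditional_entropy,
    entropy,
    gain_ratio,
    generate,
    info_gain,
    pearson_score,
    rank_features,
    relieff_weights,
    select_top,
    zscore_normalize,
)

from .oracles import joint_mutual_information, reference_relieff


class TestEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, -1, -1], 1.0),
            ([1, 1, 1, 1], 0.0),
            ([1, 1, 1, -1, -1, -1, -1, -1], 0.954434),  # H(3/8, 5/8)
        ],
    )
    def test_known_values(self, labels, expected):
        assert entropy(labels) == pytest.approx(expected, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([])


class TestConditionalEntropyAndGain:
    def test_perfect_predictor(self):
        y = [-1, -1, 1, 1]
        assert conditional_entropy([0, 0, 1, 1], y) == 0.0
        assert info_gain([0, 0, 1, 1], y) == pytest.approx(1.0)

    def test_uninformative_feature(self):
        y = [1, -1, 1, -1]
        assert conditional_entropy([2, 2, 2, 2], y) == pytest.approx(entropy(y))
        assert info_gain([2, 2, 2, 2], y) == pytest.approx(0.0)

    def test_independent_balanced_cells(self):
        assert conditional_entropy([0, 0, 1, 1], [1, -1, 1, -1]) == pytest.approx(1.0)

    def test_partial_split(self):
        # H(Y)=1, H(Y|X) = 3/4 * H(1/3, 2/3)
        assert info_gain([0, 0, 0, 1], [-1, -1, 1, 1]) == pytest.approx(
            0.311278, abs=1e-6
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            conditional_entropy([0, 1], [1, 1, -1])

    @given(st.integers(2, 10), st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_joint_distribution_oracle(self, m, data):
        """IG equals mutual information from the explicit joint table."""
        codes = data.draw(st.lists(st.integers(0, 3), min_size=m, max_size=m))
        labels = data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=m, max_size=m)
        )
        got = info_gain(np.array(codes), np.array(labels))
        assert got == pytest.approx(joint_mutual_information(codes, labels), abs=1e-12)
        # bounds: 0 <= IG <= min(H(Y), split info)
        assert 0.0 <= got <= min(entropy(labels), entropy(codes)) + 1e-12

    @given(st.integers(2, 10), st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetry_under_relabeling(self, m, data):
        codes = np.array(data.draw(st.lists(st.integers(0, 3), min_size=m, max_size=m)))
        labels = np.array(
            data.draw(st.lists(st.sampled_from([-1, 1]), min_size=m, max_size=m))
        )
        assert info_gain(codes, labels) == pytest.approx(
            info_gain(codes, -labels), abs=1e-12
        )
        # bijective renaming of bin codes
        renamed = np.array([{0: 7, 1: 5, 2: 6, 3: 9}[c] for c in codes])
        assert info_gain(renamed, labels) == pytest.approx(
            info_gain(codes, labels), abs=1e-12
        )


class TestGainRatio:
    def test_perfect_balanced_predictor(self):
        assert gain_ratio([0, 0, 1, 1], [-1, -1, 1, 1]) == pytest.approx(1.0)

    def test_constant_feature_zero_by_convention(self):
        assert gain_ratio([3, 3, 3, 3], [-1, -1, 1, 1]) == 0.0

    def test_partial_split_ratio(self):
        assert gain_ratio([0, 0, 0, 1], [-1, -1, 1, 1]) == pytest.approx(
            0.383688, abs=1e-6
        )

    @given(st.integers(2, 12), st.data())
    @settings(max_examples=100, deadline=None)
    def test_within_unit_interval(self, m, data):
        codes = data.draw(st.lists(st.integers(0, 3), min_size=m, max_size=m))
        labels = data.draw(st.lists(st.sampled_from([-1, 1]), min_size=m, max_size=m))
        assert 0.0 <= gain_ratio(np.array(codes), np.array(labels)) <= 1.0 + 1e-12


class TestPearsonScore:
    def test_values_equal_labels(self):
        assert pearson_score([1, -1, 1, -1], [1, -1, 1, -1]) == pytest.approx(1.0)

    def test_sign_symmetry(self):
        assert pearson_score([-1, 1, -1, 1], [1, -1, 1, -1]) == pytest.approx(1.0)

    def test_known_value(self):
        assert pearson_score([1, 2, 3, 4], [-1, -1, 1, 1]) == pytest.approx(
            0.894427, abs=1e-6
        )

    def test_constant_gene_scores_zero(self):
        assert pearson_score([2.0, 2.0, 2.0, 2.0], [-1, -1, 1, 1]) == 0.0


class TestRelieff:
    def test_signal_outweighs_noise(self):
        rng = np.random.default_rng(5)
        y = np.array([-1, 1] * 10)
        signal = y.astype(float)
        noise = rng.normal(size=20)
        ds = ExpressionDataset(
            values=np.column_stack([signal, noise]),
            gene_ids=np.array(["sig", "noise"], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(20)], dtype=object),
            labels=y,
        )
        w = relieff_weights(ds, k=3)
        assert w[0] > w[1]
        # cross-check against the naive reference implementation
        ref = reference_relieff(ds.values, y, k=3)
        np.testing.assert_allclose(w, ref, atol=1e-12)

    def test_constant_gene_weight_exactly_zero(self):
        rng = np.random.default_rng(0)
        y = np.array([-1, 1] * 8)
        ds = ExpressionDataset(
            values=np.column_stack([np.full(16, 3.3), rng.normal(size=16)]),
            gene_ids=np.array(["const", "g"], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(16)], dtype=object),
            labels=y,
        )
        assert relieff_weights(ds, k=2)[0] == 0.0

    def test_deterministic_given_seed(self, planted_dataset):
        ds, _ = planted_dataset
        a = relieff_weights(ds, k=5, m_iter=20, seed=11)
        b = relieff_weights(ds, k=5, m_iter=20, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_weights_bounded(self, planted_dataset):
        ds, _ = planted_dataset
        w = relieff_weights(ds, k=5)
        assert np.all(w >= -1.0) and np.all(w <= 1.0)


class TestRankFeatures:
    def test_separating_gene_is_rank_one_under_all_methods(self, planted_dataset):
        ds, planted = planted_dataset
        for method in ("ig", "gain_ratio", "correlation", "relieff"):
            ranking = rank_features(ds, method, seed=0)
            assert ranking.records[0].gene_id in planted, method

    def test_tie_break_by_canonical_order(self):
        values = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        ds = ExpressionDataset(
            values=values,
            gene_ids=np.array(["zz", "aa"], dtype=object),
            sample_ids=np.array(["a", "b", "c", "d"], dtype=object),
            labels=np.array([-1, -1, 1, 1]),
        )
        ranking = rank_features(ds, "correlation")
        # identical scores: canonical (on-disk) order wins, zz before aa
        assert ranking.gene_ids == ["zz", "aa"]

    def test_sample_permutation_invariance(self, planted_dataset):
        ds, _ = planted_dataset
        perm = np.random.default_rng(3).permutation(ds.n_samples)
        shuffled = ExpressionDataset(
            values=ds.values[perm],
            gene_ids=ds.gene_ids,
            sample_ids=ds.sample_ids[perm],
            labels=ds.labels[perm],
        )
        for method in ("ig", "gain_ratio", "correlation"):
            a = rank_features(ds, method)
            b = rank_features(shuffled, method)
            np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)
            assert a.gene_ids == b.gene_ids

    def test_noise_gene_does_not_change_other_scores(self, planted_dataset):
        ds, _ = planted_dataset
        extra = np.random.default_rng(9).normal(size=(ds.n_samples, 1))
        bigger = ExpressionDataset(
            values=np.hstack([ds.values, extra]),
            gene_ids=np.append(ds.gene_ids, "spiked_noise"),
            sample_ids=ds.sample_ids,
            labels=ds.labels,
        )
        for method in ("ig", "gain_ratio", "correlation"):
            base = {r.gene_id: r.score for r in rank_features(ds, method).records}
            grown = {r.gene_id: r.score for r in rank_features(bigger, method).records}
            for g, s in base.items():
                assert grown[g] == pytest.approx(s, abs=1e-12)

    def test_unknown_method_rejected(self, planted_dataset):
        ds, _ = planted_dataset
        with pytest.raises(ValueError, match="unknown filter method"):
            rank_features(ds, "chi2")

    def test_ranks_complete_and_scores_sorted(self, planted_dataset):
        ds, _ = planted_dataset
        ranking = rank_features(ds, "ig")
        assert [r.rank for r in ranking.records] == list(range(1, ds.n_genes + 1))
        scores = ranking.scores
        assert np.all(scores[:-1] >= scores[1:])


class TestSelectTop:
    def test_full_and_single(self, planted_dataset):
        ds, _ = planted_dataset
        ranking = rank_features(ds, "correlation")
        assert select_top(ranking, ds.n_genes) == ranking.gene_ids
        assert select_top(ranking, 1) == [ranking.records[0].gene_id]

    def test_out_of_range_rejected(self, planted_dataset):
        ds, _ = planted_dataset
        ranking = rank_features(ds, "correlation")
        for bad in (0, ds.n_genes + 1):
            with pytest.raises(ValueError):
                select_top(ranking, bad)

    def test_planted_genes_inside_top150_of_2000(self):
        ds, planted = generate(
            SyntheticSpec(m=62, n=2000, n_informative=3, effect=2.5,
                          class_balance=40 / 62, seed=42)
        )
        ds = zscore_normalize(ds)
        top = select_top(rank_features(ds, "ig"), 150)
        assert set(planted) <= set(top)
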