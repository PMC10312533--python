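import numpy as np
import pytest

from glycosim import (
    FailureCause,
    SimilarityDistribution,
    contribution_samples,
    general_comparison,
    rank_identifications,
    ranking_table,
)
from glycosim.ranking import contribution_overlap

from .conftest import make_matrix


def make_dist(values, numerators, kind="test"):
    values = np.asarray(values, dtype=float)
    return SimilarityDistribution(
        kind=kind,
        values=values,
        numerators=np.asarray(numerators, dtype=float),
        pairs=[None] * values.size,
    )


class TestGeneralComparison:
    def test_disjoint_test_below_null_is_differentiable(self):
        rng = np.random.default_rng(0)
        test = make_dist(np.clip(rng.normal(0.3, 0.03, 200), 0, 1), np.zeros((200, 1)))
        null = make_dist(np.clip(rng.normal(0.85, 0.03, 200), 0, 1), np.zeros((200, 1)), "null")
        g = general_comparison(test, null)
        assert g.alpha == pytest.approx(0.0, abs=1e-4)
        assert g.beta == pytest.approx(0.0, abs=1e-4)
        assert g.differentiable

    def test_identical_distributions_not_differentiable(self):
        vals = np.clip(np.random.default_rng(1).normal(0.7, 0.05, 300), 0, 1)
        test = make_dist(vals, np.zeros((300, 1)))
        null = make_dist(vals.copy(), np.zeros((300, 1)), "null")
        g = general_comparison(test, null)
        assert g.alpha == 0.5 and g.beta == 0.5
        assert not g.differentiable

    def test_identical_spikes_not_differentiable(self):
        test = make_dist(np.full(50, 0.9), np.zeros((50, 1)))
        null = make_dist(np.full(50, 0.9), np.zeros((50, 1)), "null")
        g = general_comparison(test, null)
        assert g.alpha == 0.5 and g.beta == 0.5 and not g.differentiable

    def test_thresholds_applied_as_strict_inequalities(self):
        rng = np.random.default_rng(2)
        # moderately separated: expect small but nonzero overlap
        test = make_dist(np.clip(rng.normal(0.5, 0.05, 500), 0, 1), np.zeros((500, 1)))
        null = make_dist(np.clip(rng.normal(0.75, 0.05, 500), 0, 1), np.zeros((500, 1)), "null")
        g = general_comparison(test, null)
        assert g.differentiable == (g.alpha < 0.05 and g.beta < 0.20)


class TestContributions:
    def test_samples_are_numerator_column(self):
        nums = np.arange(12.0).reshape(4, 3)
        dist = make_dist(np.full(4, 0.5), nums)
        assert np.array_equal(contribution_samples(dist, 1), nums[:, 1])
        with pytest.raises(IndexError):
            contribution_samples(dist, 5)

    def test_identical_datasets_contribute_squared_weighted_abundance(self, derived_matrices):
        from glycosim import build_distribution
        from glycosim.bootstrap import ResampledDataset

        a, _ = derived_matrices
        ds = ResampledDataset(source_tag="A", members=(("A", "A_r1"), ("A", "A_r2")))
        other = ResampledDataset(source_tag="A", members=(("A", "A_r1"),))
        dist = build_distribution([(ds, ds), (ds, other)], a, a, "internal_a")
        # id1 identical both sides: num = (0.6 * 1)^2 * K^0
        assert dist.numerators[0, 0] == pytest.approx(0.36, abs=1e-12)
        # id2 value 0.4 present in 1 of 2: num = (0.4*0.5)^2
        assert dist.numerators[0, 1] == pytest.approx(0.04, abs=1e-12)

    def test_decomposition_conserves_total_numerator(self, derived_matrices):
        from glycosim import modified_tanimoto, summarize_group

        a, b = derived_matrices
        sa = summarize_group(a, a.replicates)
        sb = summarize_group(b, b.replicates)
        res = modified_tanimoto(sa, sb)
        num = res.numerators.sum()
        den = sum(t.denom_a + t.denom_b for t in res.terms) - num
        assert res.total * den == pytest.approx(num, abs=1e-9)

    def test_overlap_high_for_identical_samples_low_for_separated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.05, 400).clip(0)
        assert contribution_overlap(x, x.copy()) >= 0.9
        y = rng.normal(2.0, 0.05, 400).clip(0)
        assert contribution_overlap(x, y) < 0.25


class TestRankIdentifications:
    def base_matrices(self):
        a = make_matrix([[0.5, 0.5], [0.3, 0.3], [0.2, 0.2]], group_name="A")
        b = make_matrix([[0.5, 0.5], [0.3, 0.3], [0.0, 0.0]], group_name="B",
                        replicates=["B_r1", "B_r2"])
        return a, b

    def dists_for(self, n_pairs=60, seed=0):
        rng = np.random.default_rng(seed)
        # id0: behaves identically in test and null; id1: same; id2: absent
        # from group B so its test contributions collapse to zero
        null_nums = np.column_stack([
            rng.normal(0.25, 0.01, n_pairs),
            rng.normal(0.09, 0.005, n_pairs),
            rng.normal(0.02, 0.002, n_pairs),
        ]).clip(0)
        test_nums = np.column_stack([
            rng.normal(0.25, 0.01, n_pairs),
            rng.normal(0.09, 0.005, n_pairs),
            np.zeros(n_pairs),
        ]).clip(0)
        internal_nums = np.column_stack([
            rng.normal(0.25, 0.01, n_pairs),
            rng.normal(0.09, 0.005, n_pairs),
            rng.normal(0.04, 0.002, n_pairs),
        ]).clip(0)
        mk = lambda nums, kind: make_dist(np.full(n_pairs, 0.8), nums, kind)
        return (
            mk(test_nums, "test"),
            mk(null_nums, "null"),
            mk(internal_nums, "internal_a"),
            mk(internal_nums.copy(), "internal_b"),
        )

    def test_absent_in_b_ranks_first_with_unseen_cause(self):
        a, b = self.base_matrices()
        test, null, ia, ib = self.dists_for()
        ranked = rank_identifications(test, null, ia, ib, a, b)
        assert ranked[0].id.canonical == a.ids[2].canonical
        assert ranked[0].z < -2
        assert ranked[0].failure_cause is FailureCause.UNSEEN_FILE2
        assert not ranked[0].quality_pass

    def test_null_behaved_ids_pass_quality_with_small_z(self):
        a, b = self.base_matrices()
        test, null, ia, ib = self.dists_for()
        ranked = {r.id.canonical: r for r in rank_identifications(test, null, ia, ib, a, b)}
        for i in (0, 1):
            r = ranked[a.ids[i].canonical]
            assert abs(r.z) < 2
            assert r.failure_cause is FailureCause.PASSED and r.quality_pass

    def test_ranks_ascend_with_z(self):
        a, b = self.base_matrices()
        test, null, ia, ib = self.dists_for()
        ranked = rank_identifications(test, null, ia, ib, a, b)
        assert [r.rank for r in ranked] == [1, 2, 3]
        assert ranked[0].z <= ranked[1].z <= ranked[2].z

    def test_zero_variance_null_gets_signed_sentinel(self):
        a, b = self.base_matrices()
        n = 30
        zeros = np.zeros((n, 3))
        test = make_dist(np.full(n, 0.5), np.column_stack([np.full(n, 0.2), zeros[:, 1], zeros[:, 2]]))
        null = make_dist(np.full(n, 0.5), zeros, "null")
        ia = make_dist(np.full(n, 0.5), zeros, "internal_a")
        ib = make_dist(np.full(n, 0.5), zeros, "internal_b")
        ranked = {r.id.canonical: r for r in rank_identifications(test, null, ia, ib, a, b)}
        first = ranked[a.ids[0].canonical]
        assert first.z == float("-inf") and first.degenerate_null
        # test contributions equal the constant null -> z = 0, still flagged
        second = ranked[a.ids[1].canonical]
        assert second.z == 0.0 and second.degenerate_null

    def test_ranking_table_layout(self):
        a, b = self.base_matrices()
        test, null, ia, ib = self.dists_for()
        frame = ranking_table(rank_identifications(test, null, ia, ib, a, b))
        assert list(frame.columns) == ["Glycopeptide", "ZScore", "Quality", "Likely Failure Cause"]
        assert set(frame["Quality"]) <= {"T", "F"}
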