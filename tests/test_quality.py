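import numpy as np
import pytest

from glycosim import (
    OverlapResult,
    SimilarityDistribution,
    assess_replicate_membership,
    detect_peaks,
    estimate_density,
    internal_confidence,
    typicality_check,
)
from glycosim.bootstrap import ResampledDataset


def make_dist(values, pairs=None, kind="internal_a", n_ids=1):
    values = np.asarray(values, dtype=float)
    return SimilarityDistribution(
        kind=kind,
        values=values,
        numerators=np.zeros((values.size, n_ids)),
        pairs=pairs if pairs is not None else [None] * values.size,
    )


def replicate_pairs(pair_labels, group="A"):
    """Build (dataset, dataset) pairs from lists of replicate label tuples."""
    out = []
    for left, right in pair_labels:
        d1 = ResampledDataset(source_tag=group, members=tuple((group, l) for l in left))
        d2 = ResampledDataset(source_tag=group, members=tuple((group, l) for l in right))
        out.append((d1, d2))
    return out


class TestDetectPeaks:
    def test_unimodal_gives_single_full_peak(self):
        rng = np.random.default_rng(0)
        dist = make_dist(np.clip(rng.normal(0.7, 0.03, 300), 0, 1))
        assignment = detect_peaks(estimate_density(dist), dist)
        assert assignment.n_peaks == 1
        assert assignment.masses[0] == pytest.approx(1.0)

    def test_balanced_mixture_gives_two_half_peaks(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0.3, 0.02, 150), rng.normal(0.8, 0.02, 150)])
        dist = make_dist(np.clip(vals, 0, 1))
        assignment = detect_peaks(estimate_density(dist), dist)
        assert assignment.n_peaks == 2
        assert np.allclose(assignment.masses, 0.5, atol=0.05)
        assert sum(p.n_comparisons for p in assignment.peaks) == len(dist)

    def test_spike_distribution_single_peak_at_value(self):
        dist = make_dist(np.full(20, 0.42))
        assignment = detect_peaks(estimate_density(dist), dist)
        assert assignment.n_peaks == 1
        assert assignment.peaks[0].location == pytest.approx(0.42, abs=0.01)


class TestReplicateMembership:
    def outlier_dist(self, low=0.2, n_pad=0):
        """Five single-replicate datasets, all pairwise comparisons; pairs
        involving r5 score low, everything else high. ``n_pad`` extra
        high-similarity comparisons dilute the low peak's mass."""
        reps = [f"r{i}" for i in range(1, 6)]
        labels, values = [], []
        import itertools

        for x, y in itertools.combinations(reps, 2):
            labels.append(((x,), (y,)))
            values.append(low if "r5" in (x, y) else 0.9)
        for _ in range(n_pad):
            labels.append((("r1",), ("r2",)))
            values.append(0.9)
        return make_dist(values, pairs=replicate_pairs(labels))

    def test_uniform_membership_yields_no_removals(self):
        rng = np.random.default_rng(2)
        reps = [f"r{i}" for i in range(1, 6)]
        import itertools

        labels = [((x,), (y,)) for x, y in itertools.combinations(reps, 2)]
        vals = np.clip(rng.normal(0.5, 0.3, len(labels)), 0.01, 0.99)
        dist = make_dist(vals, pairs=replicate_pairs(labels))
        assignment = detect_peaks(estimate_density(dist), dist)
        verdicts = assess_replicate_membership(assignment, dist)
        assert not any(v.remove for v in verdicts)

    def test_outlier_dominating_secondary_peak_is_removed(self):
        dist = self.outlier_dist()
        assignment = detect_peaks(estimate_density(dist), dist)
        assert assignment.multimodal
        verdicts = assess_replicate_membership(assignment, dist)
        removals = [v for v in verdicts if v.remove]
        assert removals and all(v.replicate == "r5" for v in removals)
        over = [v for v in removals if v.direction == "over"]
        assert all(v.peak_index != assignment.primary_index for v in over)

    def test_low_mass_peak_flags_without_removal(self):
        # pad the primary peak so the outlier peak holds <= 10% of comparisons
        dist = self.outlier_dist(n_pad=30)
        assignment = detect_peaks(estimate_density(dist), dist)
        verdicts = assess_replicate_membership(assignment, dist)
        flagged = [v for v in verdicts if v.replicate == "r5" and v.direction == "over"]
        assert flagged
        assert not any(v.remove for v in flagged)

    def test_fewer_than_three_replicates_warn_only(self):
        labels = [(("r1",), ("r2",))] * 4
        dist = make_dist([0.5, 0.6, 0.4, 0.55], pairs=replicate_pairs(labels))
        assignment = detect_peaks(estimate_density(dist), dist)
        verdicts = assess_replicate_membership(assignment, dist)
        assert all(not v.remove and "3 replicates" in v.note for v in verdicts)


class TestInternalConfidence:
    def test_zero_separation_fails(self):
        rng = np.random.default_rng(3)
        vals = np.clip(rng.normal(0.6, 0.05, 200), 0, 1)
        internal = make_dist(vals, kind="internal_a")
        test = make_dist(vals.copy(), kind="test")
        assessment = internal_confidence(internal, test)
        assert assessment.ic_score == pytest.approx(0.0, abs=0.05)
        assert not assessment.passes

    def test_scalar_formula_example(self):
        # mu_T=0.5, mu_I=0.8, sd_I=0.1, alpha=0.05, beta=0.10
        # -> IC = 3 * 10**-0.15 = 2.1241
        rng = np.random.default_rng(4)
        internal = make_dist(np.clip(rng.normal(0.8, 0.1, 4000), 0, 1))
        test = make_dist(np.clip(rng.normal(0.5, 0.02, 4000), 0, 1), kind="test")
        z = abs(test.mean - internal.mean) / internal.sd
        assessment = internal_confidence(
            internal, test, overlap_result=OverlapResult(crossing=0.65, alpha=0.05, beta=0.10)
        )
        assert assessment.ic_score == pytest.approx(z * 10 ** -0.15, abs=1e-9)
        assert assessment.relation == "internal_above_test"

    def test_disjoint_above_passes_with_raw_z(self):
        internal = make_dist(np.linspace(0.9, 0.95, 50))
        test = make_dist(np.linspace(0.4, 0.45, 50), kind="test")
        assessment = internal_confidence(
            internal, test, overlap_result=OverlapResult(crossing=0.7, alpha=0.0, beta=0.0)
        )
        expected = abs(test.mean - internal.mean) / internal.sd
        assert assessment.ic_score == pytest.approx(expected, abs=1e-9)
        assert assessment.passes

    def test_internal_below_test_cannot_pass(self):
        internal = make_dist(np.linspace(0.3, 0.35, 50))
        test = make_dist(np.linspace(0.8, 0.85, 50), kind="test")
        assessment = internal_confidence(
            internal, test, overlap_result=OverlapResult(crossing=0.5, alpha=0.0, beta=0.0)
        )
        assert assessment.relation == "internal_below_test"
        assert not assessment.passes


class TestTypicality:
    def test_observed_at_mean_is_typical(self):
        test = make_dist(np.linspace(0.6, 0.8, 100), kind="test")
        z, typical = typicality_check(test.mean, test)
        assert z == pytest.approx(0.0)
        assert typical

    def test_z_within_three_sd_is_typical(self):
        test = make_dist(np.linspace(0.6, 0.8, 100), kind="test")
        obs = test.mean + 1.03 * test.sd
        z, typical = typicality_check(obs, test)
        assert z == pytest.approx(1.03, abs=1e-9)
        assert typical

    def test_four_sd_away_is_atypical(self):
        test = make_dist(np.linspace(0.6, 0.8, 100), kind="test")
        z, typical = typicality_check(test.mean + 4 * test.sd, test)
        assert not typical

    def test_strict_mode_uses_interquartile_range(self):
        vals = np.concatenate([np.linspace(0.5, 0.7, 96), [0.0, 0.0, 1.0, 1.0]])
        test = make_dist(vals, kind="test")
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        _, typical_in = typicality_check((q1 + q3) / 2, test, strict=True)
        _, typical_out = typicality_check(q3 + 0.05, test, strict=True)
        assert typical_in and not typical_out

    def test_degenerate_test_distribution(self):
        test = make_dist(np.full(10, 0.9), kind="test")
        assert typicality_check(0.9, test)[1]
        assert not typicality_check(0.8, test)[1]
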