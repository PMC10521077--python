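import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcdomains.detection import RCD
from rcdomains.domino import (adjacent_value_similarity, canonical_classes,
                              classify_permutation, form_groups, one_sample_t,
                              permutation_frequencies,
                              weighted_similarity_report, RCDGroup)


def rcd(pos_mb, height, dom=0, chrom="chr1"):
    return RCD(chrom, pos_mb * 1e6, 500e3, 1.0, timing_domain_id=dom,
               replication_peak_height=float(height))


def group(heights, dom=0):
    return RCDGroup(members=[rcd(i, h, dom) for i, h in enumerate(heights)],
                    timing_domain_id=dom)


class TestGrouping:
    def test_gap_rule(self):
        rcds = [rcd(0.0, 1), rcd(1.0, 2), rcd(2.8, 3), rcd(10.0, 4)]
        groups = form_groups(rcds)
        sizes = sorted(g.n for g in groups)
        members = sorted(tuple(m.position / 1e6 for m in g.members)
                         for g in groups)
        assert sizes == [1, 1, 2]
        assert members == [(0.0, 1.0), (2.8,), (10.0,)]

    def test_domain_boundary_splits(self):
        rcds = [rcd(0.0, 1, dom=0), rcd(1.0, 2, dom=1)]
        assert all(g.n == 1 for g in form_groups(rcds))

    def test_edge_distance_variant(self):
        # centres 1.7 Mb apart but extents only 1.2 Mb apart
        rcds = [rcd(0.0, 1), rcd(1.7, 2)]
        assert [g.n for g in form_groups(rcds, distance="centre")] == [1, 1]
        assert [g.n for g in form_groups(rcds, distance="edge")] == [2]


class TestClassify:
    @pytest.mark.parametrize("heights,expected", [
        ([5, 9, 2], "2-1-3"),
        ([2, 9, 5], "2-1-3"),          # reversal symmetry
        ([1, 2, 3], "1-2-3"),          # 3-2-1 canonicalises to 1-2-3
    ])
    def test_examples(self, heights, expected):
        assert classify_permutation(group(heights)) == expected

    def test_class_counts(self):
        assert len(canonical_classes(3)) == 3
        assert len(canonical_classes(4)) == 12

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            classify_permutation(group([1, 2]))

    def test_frequencies_sum_to_100(self):
        rng = np.random.default_rng(5)
        gs = [group(rng.random(3)) for _ in range(50)]
        df = permutation_frequencies([gs], n=3)
        assert df["tp1"].sum() == pytest.approx(100.0)

    def test_perfectly_ordered_groups(self):
        gs = [group([3, 2, 1]) for _ in range(10)]
        df = permutation_frequencies([gs], n=3)
        assert df.loc["1-2-3", "tp1"] == pytest.approx(100.0)


class TestMetric:
    def test_monotone_array_value_one(self):
        res = adjacent_value_similarity([1, 2, 3, 4])
        assert res.adfa == pytest.approx(1.0)
        assert res.adfsv == pytest.approx(1.0)
        assert res.value == pytest.approx(1.0)

    def test_interleaved_array_value_minus_one(self):
        res = adjacent_value_similarity([3, 1, 4, 2])
        assert res.adfa == pytest.approx(7 / 3)
        assert res.adfsv == pytest.approx(1.0)
        assert res.madfap == pytest.approx(5 / 3)
        assert res.value == pytest.approx(-1.0)

    def test_mean_over_all_permutations_zero(self):
        vals = [adjacent_value_similarity(p).value
                for p in itertools.permutations([1, 2, 3, 4, 5])]
        assert len(vals) == 120
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_value_one_iff_monotone(self, n):
        base = list(range(1, n + 1))
        for p in itertools.permutations(base):
            v = adjacent_value_similarity(p).value
            monotone = list(p) == base or list(p) == base[::-1]
            assert (abs(v - 1.0) < 1e-12) == monotone

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=3,
                    max_size=8, unique=True),
           st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=200, deadline=None)
    def test_reversal_and_affine_invariance(self, heights, a, b):
        base = adjacent_value_similarity(heights)
        rev = adjacent_value_similarity(heights[::-1])
        aff = adjacent_value_similarity([a * h + b for h in heights])
        if base.defined:
            assert rev.value == pytest.approx(base.value, abs=1e-9)
            assert aff.value == pytest.approx(base.value, rel=1e-6, abs=1e-9)
            assert base.value <= 1.0 + 1e-12

    def test_degenerate_undefined(self):
        assert not adjacent_value_similarity([1.0, 2.0]).defined  # n = 2
        with pytest.raises(ValueError):
            adjacent_value_similarity([1.0])


class TestWeightedReport:
    def test_replication_rule(self):
        gs = [group([1, 2, 3, 5, 4]), group([5, 4, 3, 2, 1])]
        rep = weighted_similarity_report(gs)
        assert rep["weighted_values"].size == 2 * 4       # n-1 copies each
        v0 = adjacent_value_similarity([1, 2, 3, 5, 4]).value
        assert np.isclose(rep["weighted_values"], v0).sum() == 4

    def test_groups_of_three_excluded(self):
        gs = [group([1, 2, 3]) for _ in range(5)]
        with pytest.raises(ValueError):
            weighted_similarity_report(gs)

    def test_null_heights_mean_near_zero(self):
        rng = np.random.default_rng(11)
        gs = [group(rng.random(5)) for _ in range(500)]
        rep = weighted_similarity_report(gs)
        assert abs(rep["weighted"].mean) < 0.08           # ~3 SE at 500 groups

    def test_ordered_heights_positive(self):
        rng = np.random.default_rng(12)
        gs = [group(np.sort(rng.random(5))[::-1] + rng.normal(0, 0.01, 5))
              for _ in range(200)]
        rep = weighted_similarity_report(gs)
        assert rep["weighted"].mean > 0.5
        assert rep["weighted"].p < 0.05


class TestOneSampleT:
    def test_textbook_values(self):
        res = one_sample_t([2, 4, 6])
        assert res.t == pytest.approx(3.4641, rel=1e-3)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=0.002)
        assert res.ci95[0] < res.mean < res.ci95[1]

    def test_degenerate_zero_variance(self):
        res = one_sample_t([0, 0, 0, 0])
        assert res.degenerate and res.p == 1.0

    def test_ci_scales_with_values(self):
        narrow = one_sample_t([2, 4, 6])
        wide = one_sample_t([20, 40, 60])
        assert (wide.ci95[1] - wide.ci95[0]) == pytest.approx(
            10 * (narrow.ci95[1] - narrow.ci95[0]))
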