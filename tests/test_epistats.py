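"""Consensus projection, normalized levels, and the three statistical tests."""

import math

import numpy as np
import pytest
from scipy import stats

from texapt.epistats import (
    LuciferasePlate,
    dnase_proportion_test,
    homologous_regions,
    luciferase_deletion_test,
    luciferase_relative_activity,
    normalize_to_wildtype,
    normalized_level,
    one_tailed_p_from_chi2,
    paired_methylation_test,
    significance_stars,
)
from texapt.intervals import GenomicInterval
from texapt.metaprofile import TagTrack
from conftest import make_copy, oracle_consensus_positions


class TestHomologousRegions:
    def test_plus_strand_linear_map(self):
        cand = make_copy("chr1", 1000, 1300, rep_start=1, rep_end=300,
                         consensus_length=300)
        other = make_copy("chr1", 5000, 5300, rep_start=1, rep_end=300,
                          consensus_length=300)
        out = homologous_regions(cand, GenomicInterval("chr1", 1100, 1150),
                                 [cand, other])
        assert [(iv.start, iv.end) for iv in out] == [(1100, 1150), (5100, 5150)]

    def test_truncated_copy_not_covering_contributes_nothing(self):
        cand = make_copy("chr1", 1000, 1300, rep_start=1, rep_end=300,
                         consensus_length=300)
        trunc = make_copy("chr1", 7000, 7101, rep_start=200, rep_end=300,
                          consensus_length=300)
        out = homologous_regions(cand, GenomicInterval("chr1", 1100, 1150), [trunc])
        assert out == []

    def test_tfbs_outside_candidate_rejected(self):
        cand = make_copy("chr1", 1000, 1300)
        with pytest.raises(ValueError):
            homologous_regions(cand, GenomicInterval("chr1", 2000, 2050), [cand])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_base_oracle(self, rng, strand):
        """Lifted interval equals the exact preimage of the consensus footprint
        under the per-base map, on copies with scaling and truncation."""
        cand = make_copy("chr1", 1000, 1250, rep_start=11, rep_end=260,
                         consensus_length=300)
        tfbs = GenomicInterval("chr1", 1060, 1140)
        fp = oracle_consensus_positions(cand)
        a = min(fp[1060], fp[1139]); b = max(fp[1060], fp[1139])
        for k in range(25):
            rs = int(rng.integers(1, 150))
            re = int(rng.integers(rs + 30, 301))
            glen = int(rng.integers(re - rs + 1 - 20, re - rs + 1 + 40))
            glen = max(glen, 30)
            copy = make_copy("chr1", 5000, 5000 + glen, strand=strand,
                             rep_start=rs, rep_end=re, consensus_length=300)
            lifted = homologous_regions(cand, tfbs, [copy])
            cmap = oracle_consensus_positions(copy)
            expected = sorted(g for g in cmap if a <= cmap[g] <= b)
            if not expected:
                assert lifted == []
            else:
                (iv,) = lifted
                assert (iv.start, iv.end) == (expected[0], expected[-1] + 1)

    def test_idempotent_and_bounded(self):
        cand = make_copy("chr1", 1000, 1300, rep_start=1, rep_end=300,
                         consensus_length=300)
        tfbs = GenomicInterval("chr1", 1100, 1150)
        copies = [make_copy("chr1", 5000, 5150, strand="-", rep_start=76,
                            rep_end=225, consensus_length=300)]
        first = homologous_regions(cand, tfbs, copies)
        for iv, host in zip(first, copies):
            assert host.interval.contains(iv)
        # projecting the candidate's own lifted footprint again changes nothing
        (self_iv,) = homologous_regions(cand, tfbs, [cand])
        again = homologous_regions(cand, self_iv, copies)
        assert again == first


class TestNormalizedLevel:
    def test_ratio_and_sole_copy_identity(self):
        tags = [GenomicInterval("chr1", 100 + i * 10, 130 + i * 10) for i in range(50)]
        track = TagTrack("t", tags, total_mapped=50)
        cand = [GenomicInterval("chr1", 100, 150)]
        subfam = [GenomicInterval("chr1", 100, 700)]
        level = normalized_level(cand, subfam, track)
        direct = len([t for t in tags if t.start < 150 and t.end > 100])
        assert level == pytest.approx(direct / 50)
        assert normalized_level(cand, cand, track) == 1.0

    def test_zero_denominator_rejected(self):
        track = TagTrack("t", [GenomicInterval("chr1", 0, 30)], total_mapped=1)
        with pytest.raises(ValueError):
            normalized_level([GenomicInterval("chr2", 0, 10)],
                             [GenomicInterval("chr2", 0, 10)], track)


class TestPairedMethylationTest:
    def test_matches_scipy_one_sided(self, rng):
        pairs = [(float(t), float(n))
                 for t, n in rng.normal(0.4, 0.1, size=(6, 2))]
        res = paired_methylation_test(pairs)
        d = [t - n for t, n in pairs]
        ref = stats.ttest_1samp(d, 0.0, alternative="less")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 5

    def test_symmetric_pairs_give_half(self):
        pairs = [(0.5, 0.4), (0.4, 0.5), (0.6, 0.3), (0.3, 0.6)]
        res = paired_methylation_test(pairs)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_degenerate_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_methylation_test([(0.5, 0.4), (0.6, 0.5), (0.3, 0.2)])


class TestDnaseProportionTest:
    def test_equal_proportions_give_half(self):
        res = dnase_proportion_test(50, 1000, 100, 2000)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_yates_formula_on_small_counts(self):
        x1, n1, x2, n2 = 30, 100, 15, 100
        a, b, c, d = x1, n1 - x1, x2, n2 - x2
        N = n1 + n2
        expected_chi2 = (
            N * (abs(a * d - b * c) - N / 2) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        res = dnase_proportion_test(x1, n1, x2, n2)
        assert res.statistic == pytest.approx(expected_chi2)

    def test_one_tailed_halves_two_sided_when_direction_matches(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(50, 500)), int(rng.integers(50, 500))
            x1 = int(rng.integers(1, n1))
            x2 = int(rng.integers(0, max(1, int(x1 / n1 * n2))))  # p1 >= p2 mostly
            res = dnase_proportion_test(x1, n1, x2, n2, direction="greater")
            p_two = stats.chi2.sf(res.statistic, 1)
            if x1 / n1 > x2 / n2 and res.statistic > 0:
                assert res.p_value == pytest.approx(p_two / 2)
            res_wrong = dnase_proportion_test(x1, n1, x2, n2, direction="less")
            if x1 / n1 > x2 / n2 and res.statistic > 0:
                assert res_wrong.p_value == pytest.approx(1 - p_two / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dnase_proportion_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            dnase_proportion_test(11, 10, 1, 10)


class TestLuciferase:
    def plates(self, effects, noise=1.0):
        return [
            LuciferasePlate(name, tuple(1e5 * e * noise for _ in range(3)),
                            (1e4, 1e4, 1e4), 1)
            for name, e in effects.items()
        ]

    def test_positive_control_normalizes_to_one(self):
        acts = luciferase_relative_activity(
            self.plates({"wild-type": 1.0, "positive control": 2.0})
        )
        assert acts["positive control"] == pytest.approx(1.0)
        assert acts["wild-type"] == pytest.approx(0.5)

    def test_half_firefly_gives_half_activity(self):
        acts = luciferase_relative_activity(
            self.plates({"wild-type": 1.0, "TE-deleted": 0.5,
                         "positive control": 2.0})
        )
        assert acts["TE-deleted"] == pytest.approx(acts["wild-type"] / 2)

    def test_wildtype_normalization_across_experiments(self):
        per_exp = [{"wild-type": 0.5, "TE-deleted": 0.1},
                   {"wild-type": 0.7, "TE-deleted": 0.2}]
        norm = normalize_to_wildtype(per_exp)
        assert np.mean(norm["wild-type"]) == pytest.approx(1.0)
        assert norm["TE-deleted"] == pytest.approx([0.1 / 0.6, 0.2 / 0.6])

    def test_identical_samples_give_half(self):
        res = luciferase_deletion_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)
        assert res.df == 4

    def test_extreme_shift_highly_significant(self):
        wt = [1.0, 1.05, 0.95]
        pooled_sd = np.std(wt + wt, ddof=1)
        deleted = [w - 10 * pooled_sd for w in wt]
        res = luciferase_deletion_test(wt, deleted)
        assert res.p_value < 0.001
        assert significance_stars(res.p_value) == "***"

    def test_matches_pooled_variance_formula(self, rng):
        wt = rng.normal(1.0, 0.1, 3).tolist()
        dele = rng.normal(0.6, 0.1, 3).tolist()
        res = luciferase_deletion_test(wt, dele)
        n1, n2 = 3, 3
        sp2 = ((n1 - 1) * np.var(dele, ddof=1) + (n2 - 1) * np.var(wt, ddof=1)) / (
            n1 + n2 - 2
        )
        t_ref = (np.mean(dele) - np.mean(wt)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(t_ref)
        assert res.p_value == pytest.approx(stats.t.cdf(t_ref, 4))


def test_chi2_helper_matches_direct_tail():
    assert one_tailed_p_from_chi2(7.88) == pytest.approx(stats.chi2.sf(7.88, 1) / 2)
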