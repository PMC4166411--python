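"""Fold changes, resampling null, rank-sum test, background and metaplots."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from cgifaire import (
    FragmentSet,
    GenomeDict,
    GenomicInterval,
    IntervalSet,
    aggregate_profile,
    fold_change_values,
    fold_changes,
    genome_background,
    rank_sum_test,
    resampling_null,
)


def enumerate_rank_sum_p(x, y):
    """Two-sided rank-sum p by full enumeration over rank assignments.

    Independent brute-force reference for tie-free samples: every C(n, n1)
    assignment of the combined ranks to the first sample, two-sided via
    min(U1, U2).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min_obs = min(u1_obs, n1 * n2 - u1_obs)
    count = sum(
        min(u1 := sum(sub) - n1 * (n1 + 1) / 2, n1 * n2 - u1) <= u_min_obs
        for sub in itertools.combinations(range(1, n1 + n2 + 1), n1)
    )
    return count / comb(n1 + n2, n1)


def uniform_fragset(rng, n, chrom_len=100_000, frag_len=100, condition=""):
    starts = rng.integers(0, chrom_len - frag_len, n)
    g = GenomeDict({"chr1": chrom_len})
    return FragmentSet.from_intervals(
        [GenomicInterval("chr1", int(s), int(s) + frag_len) for s in starts],
        condition=condition,
        genome=g,
    )


class TestFoldChanges:
    def _sets(self, counts_a, counts_b, lib_a=None, lib_b=None):
        """Fragment sets hitting one region [0,100) with given counts."""
        region = GenomicInterval("chr1", 0, 100)
        fa = [GenomicInterval("chr1", 0, 100)] * counts_a + [
            GenomicInterval("chr1", 5000, 5100)
        ] * ((lib_a or counts_a) - counts_a)
        fb = [GenomicInterval("chr1", 0, 100)] * counts_b + [
            GenomicInterval("chr1", 5000, 5100)
        ] * ((lib_b or counts_b) - counts_b)
        return region, FragmentSet.from_intervals(fa), FragmentSet.from_intervals(fb)

    def test_equal_libraries_ratio(self):
        region, fa, fb = self._sets(20, 10, lib_a=100, lib_b=100)
        (sig,) = fold_changes([region], fa, fb, pseudocount=0)
        assert sig.fold_change == pytest.approx(2.0)

    def test_normalization_forced(self):
        # 10 of 2M-scale vs 10 of 1M-scale library
        fa = FragmentSet(
            "a", {"chr1": (np.zeros(10, int), np.full(10, 100))}, library_size=2_000_000
        )
        fb = FragmentSet(
            "b", {"chr1": (np.zeros(10, int), np.full(10, 100))}, library_size=1_000_000
        )
        (sig,) = fold_changes([GenomicInterval("chr1", 0, 100)], fa, fb, pseudocount=0)
        assert sig.signal_a == pytest.approx(5.0)
        assert sig.signal_b == pytest.approx(10.0)
        assert sig.fold_change == pytest.approx(0.5)

    def test_identical_conditions_unity(self, rng):
        fs = uniform_fragset(rng, 500)
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 800) for i in range(20)]
        fc = fold_change_values(regions, fs, fs, pseudocount=1)
        assert np.allclose(fc, 1.0)

    def test_zero_control_with_zero_pseudocount_errors(self):
        fa = FragmentSet.from_intervals([GenomicInterval("chr1", 0, 100)])
        fb = FragmentSet.from_intervals([GenomicInterval("chr1", 5000, 5100)])
        with pytest.raises(ValueError, match="chr1:0-100"):
            fold_changes([GenomicInterval("chr1", 0, 100)], fa, fb, pseudocount=0)

    def test_invariant_to_file_split_and_order(self, rng):
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 9000, 400)
        ]
        regions = [GenomicInterval("chr1", i * 500, i * 500 + 400) for i in range(15)]
        fb = uniform_fragset(rng, 400, chrom_len=10_000)
        whole = FragmentSet.from_intervals(frags)
        split = FragmentSet.from_intervals(frags[200:] + frags[:200])
        assert np.array_equal(
            fold_change_values(regions, whole, fb),
            fold_change_values(regions, split, fb),
        )

    def test_monotone_in_treatment_count(self):
        # library size held fixed with filler fragments elsewhere
        region = GenomicInterval("chr1", 0, 100)
        filler = GenomicInterval("chr1", 5000, 5100)
        fb = FragmentSet.from_intervals([GenomicInterval("chr1", 0, 100)] * 5)
        fc = []
        for k in (3, 4, 5):
            fa = FragmentSet.from_intervals(
                [GenomicInterval("chr1", 0, 100)] * k + [filler] * (10 - k)
            )
            fc.append(fold_change_values([region], fa, fb)[0])
        assert fc[0] < fc[1] < fc[2]


class TestResamplingNull:
    def test_identical_conditions_degenerate_at_one(self, rng):
        fs = uniform_fragset(rng, 2000)
        null = resampling_null(
            fs, fs, fs.genome, n_regions=50, region_length=1000, n_draws=4, seed=1
        )
        assert np.allclose(null.pooled, 1.0)

    def test_bookkeeping(self, rng):
        fa = uniform_fragset(rng, 500)
        fb = uniform_fragset(rng, 500)
        null = resampling_null(
            fa, fb, fa.genome, n_regions=3, region_length=1000, n_draws=2, seed=5
        )
        assert null.pooled.size == 6
        assert null.draw_medians.size == 2

    def test_deterministic_for_seed(self, rng):
        fa = uniform_fragset(rng, 500)
        fb = uniform_fragset(rng, 500)
        a = resampling_null(fa, fb, fa.genome, 20, 500, 3, seed=9)
        b = resampling_null(fa, fb, fa.genome, 20, 500, 3, seed=9)
        assert np.array_equal(a.pooled, b.pooled)

    def test_global_doubling_recovered(self, rng):
        # absolute-scale comparison: treatment fragments duplicated but the
        # normalisation denominator held fixed (spike-in style), so the
        # uniform 2x accessibility gain is visible as fold change ~2
        fb = uniform_fragset(rng, 5000)
        doubled = [iv for iv in fb] * 2
        fa = FragmentSet.from_intervals(doubled, genome=fb.genome)
        fa.library_size = fb.library_size
        null = resampling_null(fa, fb, fb.genome, 1000, 1000, 10, seed=2)
        assert 1.9 <= np.median(null.pooled) <= 2.1


class TestRankSum:
    def test_minimum_rank_sum_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 20)

    def test_identical_samples_midranks(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p == 1.0

    def test_degenerate_constant(self):
        res = rank_sum_test([5, 5], [5, 5, 5])
        assert res.method == "degenerate"
        assert res.p == 1.0

    def test_strong_separation(self, rng):
        x = rng.normal(1, 0.1, 100)
        y = rng.normal(3, 0.1, 100)
        res = rank_sum_test(x, y)
        assert res.method == "normal"
        assert res.p < 1e-10

    def test_exact_matches_enumeration(self, rng):
        for n in (3, 5, 8):
            for _ in range(5):
                x = rng.normal(0, 1, n)
                y = rng.normal(0.5, 1, n)
                res = rank_sum_test(x, y, method="exact")
                assert res.p == pytest.approx(enumerate_rank_sum_p(x, y))

    def test_normal_approx_close_to_exact_n8(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.8, 1, 8)
            approx = rank_sum_test(x, y, method="normal")
            assert abs(approx.p - enumerate_rank_sum_p(x, y)) <= 0.01

    def test_p_display_floor(self):
        from cgifaire.accessibility_stats import RankSumResult

        r = RankSumResult(u=0, z=-50.0, p=0.0, n1=10, n2=10, method="normal")
        assert r.p_display == "< 1e-300"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestGenomeBackground:
    def test_identical_conditions_zero_lfc(self, rng):
        fs = uniform_fragset(rng, 2000)
        bg = genome_background(fs, fs, fs.genome, window=1000, step=50)
        assert np.allclose(bg.log2_fold_change, 0.0)

    def test_window_tiling_count(self, rng):
        g = GenomeDict({"chr1": 1100})
        fs = FragmentSet.from_intervals(
            [GenomicInterval("chr1", 0, 1100)], genome=g
        )
        bg = genome_background(fs, fs, g, window=1000, step=50)
        assert bg.log2_fold_change.size == 3

    def test_empty_windows_excluded(self, rng):
        g = GenomeDict({"chr1": 10_000})
        fs = FragmentSet.from_intervals([GenomicInterval("chr1", 0, 100)], genome=g)
        bg = genome_background(fs, fs, g, window=1000, step=1000)
        assert bg.log2_fold_change.size + bg.n_excluded == 10

    def test_site_specific_elevation(self, small_dataset):
        """Elevation is confined to peaked sites: windows fully inside
        strongly-responding sites show log2 FC > 1, background windows ~0."""
        ds = small_dataset
        bg = genome_background(
            ds.fragments["UNC0638"], ds.fragments["DMSO"], ds.genome,
            window=500, step=100,
        )
        peak_spans = {c: [] for c in ds.genome}
        for iv in ds.peaks:
            peak_spans[iv.chrom].append((iv.start, iv.end))
        truth = ds.truth
        strong = {
            (r.chrom, r.start, r.end)
            for r in truth[truth.true_ratio >= 4.0].itertuples()
        }
        in_strong = np.zeros(bg.log2_fold_change.size, dtype=bool)
        in_any_peak = np.zeros(bg.log2_fold_change.size, dtype=bool)
        for i, (c, s) in enumerate(zip(bg.chroms, bg.starts)):
            w = (s, s + bg.window)
            for ps, pe in peak_spans[c]:
                if ps < w[1] and w[0] < pe:
                    in_any_peak[i] = True
            for sc, ss, se in strong:
                if sc == c and ss <= w[0] and w[1] <= se:
                    in_strong[i] = True
        assert abs(np.median(bg.log2_fold_change[~in_any_peak])) < 0.1
        assert np.median(bg.log2_fold_change[in_strong]) > 1.0


class TestAggregateProfile:
    def test_uniform_tiling_is_flat(self):
        g = GenomeDict({"chr1": 100_000})
        frags = [GenomicInterval("chr1", s, s + 100) for s in range(0, 100_000, 100)]
        fs = FragmentSet.from_intervals(frags, genome=g)
        regions = [GenomicInterval("chr1", 40_000, 41_000)]
        prof = aggregate_profile(regions, fs, flank=2000, bin=100)
        assert np.all(prof.mean_signal == prof.mean_signal[0])

    def test_center_peak_symmetric(self):
        g = GenomeDict({"chr1": 100_000})
        mid = 50_000
        frags = [
            GenomicInterval("chr1", mid - off - 50, mid + off + 50)
            for off in range(0, 500, 10)
        ]
        fs = FragmentSet.from_intervals(frags, genome=g)
        regions = [GenomicInterval("chr1", mid - 1000, mid + 1000)]
        prof = aggregate_profile(regions, fs, flank=2000, bin=100)
        assert np.argmax(prof.mean_signal) in (len(prof.mean_signal) // 2 - 1,
                                               len(prof.mean_signal) // 2)
        assert np.allclose(prof.mean_signal, prof.mean_signal[::-1])

    def test_empty_regions_error(self, rng):
        fs = uniform_fragset(rng, 100)
        with pytest.raises(ValueError):
            aggregate_profile([], fs)

    def test_edge_regions_skipped(self, rng):
        fs = uniform_fragset(rng, 100)  # chrom length 100 kb
        regions = [
            GenomicInterval("chr1", 100, 200),  # too close to the start
            GenomicInterval("chr1", 50_000, 51_000),
        ]
        prof = aggregate_profile(regions, fs, flank=5000, bin=100)
        assert prof.n_regions == 1 and prof.n_skipped == 1

    def test_flank_must_be_bin_multiple(self, rng):
        fs = uniform_fragset(rng, 100)
        with pytest.raises(ValueError):
            aggregate_profile([GenomicInterval("chr1", 50_000, 51_000)], fs,
                              flank=1050, bin=100)
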