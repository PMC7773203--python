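"""Peak-caller unit tests: binning, background stats, thresholding,
merging, replicate consensus, and equivalence with a brute-force reference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _reference import ref_merge, ref_pipeline_consensus
from gcn4scope.core_io import FragmentSet
from gcn4scope.peakcall import (
    BinnedCoverage,
    Peak,
    PeakSet,
    background_stats,
    bin_counts,
    call_regions,
    call_sample_peaks,
    consensus_peaks,
    merge_regions,
    normalize_bins,
    replicate_correlation,
)


def _cov(counts, bin_size=100, chrom="chrI"):
    arr = np.asarray(counts, dtype=np.int64)
    return BinnedCoverage(
        sample_id="t", bin_size=bin_size,
        counts={chrom: arr}, chrom_sizes={chrom: len(arr) * bin_size},
    )


class TestBinCounts:
    def test_midpoint_assignment(self):
        frags = FragmentSet("s", [("chrI", 5, 15), ("chrI", 140, 160), ("chrI", 240, 260)])
        cov = bin_counts(frags, {"chrI": 300}, bin_size=100)
        assert cov.counts["chrI"].tolist() == [1, 1, 1]

    def test_midpoint_on_boundary_goes_right(self):
        """Midpoint exactly 100 falls in bin 1 (half-open bins)."""
        frags = FragmentSet("s", [("chrI", 90, 110)])
        cov = bin_counts(frags, {"chrI": 300}, bin_size=100)
        assert cov.counts["chrI"].tolist() == [0, 1, 0]

    def test_truncated_terminal_bin_counted(self):
        frags = FragmentSet("s", [("chrI", 240, 248)])
        cov = bin_counts(frags, {"chrI": 250}, bin_size=100)
        assert len(cov.counts["chrI"]) == 3 and cov.counts["chrI"][2] == 1

    @given(st.lists(st.integers(0, 990), min_size=1, max_size=50))
    def test_conservation(self, midpoints):
        frags = FragmentSet("s", [("chrI", m, m + 10) for m in midpoints])
        cov = bin_counts(frags, {"chrI": 1000}, bin_size=100)
        assert cov.counts["chrI"].sum() == len(midpoints)

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            bin_counts(FragmentSet("s", [("chrZ", 0, 10)]), {"chrI": 300})


class TestBackgroundStats:
    def test_hand_enumerated_vector(self):
        """counts [0,0,1,1,1,2,5]: mu=1, x=0, divisor=1 (hand enumeration)."""
        bg = background_stats(_cov([0, 0, 1, 1, 1, 2, 5]), min_bins=1)
        assert (bg.mu, bg.x, bg.divisor) == (1, 0.0, 1.0)
        assert bg.n_background_bins == 3

    def test_all_equal_plus_outlier(self):
        """counts [2,2,2,2,9]: mu=2, divisor=2."""
        bg = background_stats(_cov([2, 2, 2, 2, 9]), min_bins=1)
        assert bg.mu == 2 and bg.divisor == 2.0

    def test_mode_tie_takes_smallest(self):
        bg = background_stats(_cov([1, 1, 3, 3, 9]), min_bins=1)
        assert bg.mu == 1

    def test_null_simulation_divisor_near_true_mean(self, null_sim):
        """On peak-free data the divisor estimates the mean background count."""
        sizes = null_sim["chrom_sizes"]
        mock = null_sim["chip"][-1]
        cov = bin_counts(mock, sizes)
        true_mean = mock.total_count / cov.n_bins
        bg = background_stats(cov)
        assert abs(bg.divisor - true_mean) / true_mean < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            background_stats(_cov([1, 2, 3]))

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            background_stats(_cov([5] * 200))


class TestNormalizeAndCall:
    def test_normalization_arithmetic(self):
        cov = _cov([6, 0, 2])
        bg = background_stats(_cov([2, 2, 2, 2, 9]), min_bins=1)
        norm = normalize_bins(cov, bg)
        assert norm["chrI"].tolist() == [3.0, 0.0, 1.0]

    def test_background_bins_average_near_one_on_null(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(80, size=5000)
        cov = _cov(counts)
        bg = background_stats(cov)
        norm = normalize_bins(cov, bg)["chrI"]
        mask = (counts >= bg.mu - bg.x) & (counts <= bg.mu + bg.x)
        assert 0.9 < norm[mask].mean() < 1.1

    def test_run_to_interval(self):
        norm = {"chrI": np.array([0.5, 2.5, 2.1, 0.1])}
        regions = call_regions(norm, {"chrI": 400}, bin_size=100)
        assert [(c, s, e) for c, s, e, _ in regions] == [("chrI", 100, 300)]

    def test_threshold_is_strict(self):
        """A bin normalized to exactly 2.0 is excluded ('above 2')."""
        norm = {"chrI": np.array([2.0, 2.0001, 2.0])}
        regions = call_regions(norm, {"chrI": 300}, bin_size=100)
        assert [(s, e) for _, s, e, _ in regions] == [(100, 200)]

    def test_all_sub_threshold_empty(self):
        assert call_regions({"chrI": np.array([0.1, 1.9])}, {"chrI": 200}, 100) == []


class TestMergeRegions:
    def test_gap_below_200_merges(self):
        merged = merge_regions([("chrI", 1000, 1100, 2.5), ("chrI", 1250, 1350, 3.0)])
        assert [(s, e) for _, s, e, _ in merged] == [(1000, 1350)]
        assert merged[0][3] == 3.0  # max signal of members

    def test_gap_exactly_200_not_merged(self):
        merged = merge_regions([("chrI", 1000, 1100, 1), ("chrI", 1300, 1400, 1)])
        assert len(merged) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 400)), min_size=0, max_size=20
        ),
        st.integers(1, 300),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_and_idempotent(self, raw, gap):
        regions = [("chrI", s, s + w, 0.0) for s, w in raw]
        merged = merge_regions(regions, gap)
        # idempotence
        assert merge_regions(merged, gap) == merged
        # order invariance
        assert merge_regions(list(reversed(regions)), gap) == merged
        # brute-force transitive closure oracle
        assert [(s, e) for _, s, e, _ in merged] == ref_merge(
            [(s, e) for _, s, e, _ in regions], gap
        )


class TestConsensus:
    def _ps(self, intervals, source):
        return PeakSet(
            peaks=[
                Peak("chrI", s, e, peak_id=f"{source}{i}", signal=1.0, source=source)
                for i, (s, e) in enumerate(intervals)
            ]
        )

    def test_overlap_below_min_rejected(self):
        cons = consensus_peaks(self._ps([(100, 300)], "A"), self._ps([(260, 400)], "B"))
        assert len(cons) == 0  # overlap 40 < 50

    def test_overlap_exactly_min_accepted_as_union(self):
        cons = consensus_peaks(self._ps([(100, 300)], "A"), self._ps([(250, 400)], "B"))
        assert [(p.start, p.end) for p in cons] == [(100, 400)]

    def test_empty_replicate_gives_empty_consensus(self):
        cons = consensus_peaks(self._ps([], "A"), self._ps([(0, 100)], "B"))
        assert len(cons) == 0

    def test_chained_unions_merge(self):
        cons = consensus_peaks(
            self._ps([(0, 100), (150, 260)], "A"), self._ps([(40, 200)], "B")
        )
        assert [(p.start, p.end) for p in cons] == [(0, 260)]
        assert "A0" in cons.peaks[0].source and "A1" in cons.peaks[0].source


class TestReplicateCorrelation:
    def test_identical_replicates_r_one(self):
        rng = np.random.default_rng(0)
        cov = _cov(rng.poisson(50, 500))
        assert replicate_correlation(cov, cov) == pytest.approx(1.0)

    def test_independent_null_near_zero(self):
        rng = np.random.default_rng(1)
        a = _cov(rng.poisson(50, 10_000))
        b = _cov(rng.poisson(50, 10_000))
        assert abs(replicate_correlation(a, b)) < 0.05

    def test_true_replicates_highly_correlated(self, default_sim):
        sizes = default_sim["chrom_sizes"]
        ip1, ip2 = default_sim["chip"][0], default_sim["chip"][1]
        r = replicate_correlation(bin_counts(ip1, sizes), bin_counts(ip2, sizes))
        assert r > 0.8

    def test_zero_variance_rejected(self):
        cov = _cov([3] * 200)
        with pytest.raises(ValueError):
            replicate_correlation(cov, cov, normalized=False)


class TestEndToEndVsReference:
    def _random_sample(self, rng, chrom_len, hotspots):
        n_bg = int(rng.integers(1500, 4000))
        mids = list(rng.integers(0, chrom_len - 1, size=n_bg))
        for pos, width, fold in hotspots:
            extra = rng.poisson((fold - 1) * n_bg * width / chrom_len)
            mids += list(rng.integers(pos, min(pos + width, chrom_len - 1), size=extra))
        return [(int(m), int(m) + 2) for m in mids]

    def test_consensus_equals_brute_force_reference(self):
        """Pipeline peak calls match a direct transcription of the method
        (binning, mode/MAD normalization, strict >2, <200 merge, >=50 consensus)
        on random small genomes."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            chrom_len = 10_000
            hotspots = [
                (int(rng.integers(0, chrom_len - 400)), int(rng.integers(200, 400)),
                 float(rng.uniform(2, 12)))
                for _ in range(rng.integers(0, 4))
            ]
            raw = [self._random_sample(rng, chrom_len, hotspots) for _ in range(2)]
            frag_sets = [
                FragmentSet(f"rep{i}", [("chrI", s, e) for s, e in frags])
                for i, frags in enumerate(raw)
            ]
            ours = consensus_peaks(
                call_sample_peaks(frag_sets[0], {"chrI": chrom_len}),
                call_sample_peaks(frag_sets[1], {"chrI": chrom_len}),
            )
            ref = ref_pipeline_consensus(raw[0], raw[1], chrom_len)
            assert [(p.start, p.end) for p in ours] == ref
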