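"""Simulator tests: determinism, planted structure, distributional checks."""

import numpy as np
import pytest

from gcn4scope.annotate import scan_motif
from gcn4scope.composition import bin_proteome, rk_fraction
from gcn4scope.synthetic_data import (
    SyntheticTruth,
    make_genes,
    make_genome,
    plant_motifs_and_peaks,
    simulate_all,
    simulate_chip,
    simulate_de_counts,
    simulate_proteome,
)


class TestMakeGenome:
    def test_deterministic_given_seed(self):
        g1, s1 = make_genome(1, 100_000, 0.38, seed=7)
        g2, s2 = make_genome(1, 100_000, 0.38, seed=7)
        assert g1 == g2 and s1 == s2

    def test_distinct_seeds_differ(self):
        g1, _ = make_genome(1, 10_000, 0.38, seed=7)
        g2, _ = make_genome(1, 10_000, 0.38, seed=8)
        assert g1 != g2

    def test_gc_within_binomial_bound(self):
        """Observed GC within 3 sd of Binomial(n, 0.5)."""
        genome, _ = make_genome(1, 100_000, 0.5, seed=1)
        seq = genome["chrI"]
        gc = seq.count("G") + seq.count("C")
        sd = (100_000 * 0.25) ** 0.5
        assert abs(gc - 50_000) < 3 * sd

    def test_chrom_sizes_match(self):
        _, sizes = make_genome(2, 50_000, 0.4, seed=0)
        assert len(sizes) == 2 and sum(sizes.values()) == 100_000

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            make_genome(1, 100_000, 1.5, seed=0)


class TestMakeGenes:
    def test_requested_count_non_overlapping(self):
        ann = make_genes({"chrI": 100_000}, n_genes=50, seed=3)
        assert len(ann.genes) == 50
        spans = sorted((g.chrom, min(g.tss, g.tts), max(g.tss, g.tts)) for g in ann.genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_utr5_offset_range(self):
        ann = make_genes({"chrI": 200_000}, n_genes=40, utr5_range=(50, 200), seed=1)
        for g in ann.genes:
            off = g.orf_start - g.tss if g.strand == "+" else g.tss - (g.orf_end - 1)
            assert 50 <= off <= 200

    def test_deterministic(self):
        a = make_genes({"chrI": 100_000}, n_genes=30, seed=9)
        b = make_genes({"chrI": 100_000}, n_genes=30, seed=9)
        assert a.genes == b.genes

    def test_genome_too_small_error_names_requirement(self):
        with pytest.raises(ValueError, match="bp"):
            make_genes({"chrI": 10_000}, n_genes=500, seed=0)


class TestPlanting:
    @pytest.fixture()
    def planted(self):
        genome, sizes = make_genome(1, 100_000, 0.38, seed=2)
        ann = make_genes(sizes, n_genes=30, seed=2)
        targets = {g.gene_id for g in ann.genes[:8]}
        genome2, truth = plant_motifs_and_peaks(genome, ann, targets, seed=2)
        return genome2, ann, targets, truth

    def test_motif_planted_in_promoter_window(self, planted):
        genome2, ann, targets, truth = planted
        by_gene = {g.gene_id: g for g in ann.genes}
        assert len(truth.motif_positions) == len(targets)
        for (chrom, pos, strand), gid in zip(truth.motif_positions, sorted(targets)):
            g = by_gene[gid]
            if g.strand == "+":
                lo, hi = g.tss - 1000, g.tss + 100
            else:
                lo, hi = g.tss - 100, g.tss + 1000
            assert max(0, lo) <= pos <= hi

    def test_planted_instance_found_by_scanner(self, planted):
        genome2, _, _, truth = planted
        for chrom, pos, strand in truth.motif_positions:
            window = genome2[chrom][pos : pos + 7]
            hits = scan_motif(window)
            assert any(h.pos == 0 for h in hits)

    def test_peaks_centered_on_motifs(self, planted):
        _, _, _, truth = planted
        for (chrom, start, end, fold), (_, pos, _) in zip(
            truth.planted_peaks, truth.motif_positions
        ):
            assert start <= pos < end and 200 <= end - start <= 400


class TestTruthClasses:
    def test_five_way_partition(self, default_sim):
        truth, ann = default_sim["truth"], default_sim["annotation"]
        sets = [
            truth.direct_activated,
            truth.direct_repressed,
            truth.indirect_activated,
            truth.indirect_repressed,
            truth.null_genes,
        ]
        union = set().union(*sets)
        assert union == ann.gene_ids()
        assert sum(len(s) for s in sets) == len(union)  # pairwise disjoint

    def test_direct_genes_near_peaks_others_not(self, default_sim):
        truth, ann = default_sim["truth"], default_sim["annotation"]

        def near_peak(g):
            return any(
                g.chrom == c and g.orf_start < e + 750 and s - 750 < g.orf_end
                for c, s, e, _ in truth.planted_peaks
            )

        for g in ann.genes:
            direct = g.gene_id in truth.direct_activated | truth.direct_repressed
            assert near_peak(g) == direct

    def test_truth_json_roundtrip(self, default_sim, tmp_path):
        truth = default_sim["truth"]
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.planted_peaks == truth.planted_peaks
        assert back.direct_activated == truth.direct_activated
        assert back.rk_bins_truth == truth.rk_bins_truth


class TestSimulateChip:
    def test_returns_reps_plus_mock(self, default_sim):
        chip = default_sim["chip"]
        assert len(chip) == 3
        assert [f.sample_id for f in chip] == ["IP_rep1", "IP_rep2", "mock"]

    def test_depth_preserved(self, default_sim):
        assert all(f.total_count == 200_000 for f in default_sim["chip"])

    def test_peak_fragment_count_matches_poisson_expectation(self, default_sim):
        """Fragments inside a planted peak ~ enrichment x background, within 3 sd."""
        truth = default_sim["truth"]
        ip = default_sim["chip"][0]
        genome_len = sum(default_sim["chrom_sizes"].values())
        peak_bp = sum(e - s for _, s, e, _ in truth.planted_peaks)
        fold = truth.planted_peaks[0][3]
        total_weight = genome_len + (fold - 1) * peak_bp
        for chrom, start, end, f in truth.planted_peaks[:5]:
            expected = 200_000 * f * (end - start) / total_weight
            observed = sum(
                1 for c, s, e in ip.fragments if c == chrom and start <= (s + e) // 2 < end
            )
            assert abs(observed - expected) < 3 * expected**0.5

    def test_mock_is_pure_background(self, default_sim):
        truth = default_sim["truth"]
        mock = default_sim["chip"][-1]
        genome_len = sum(default_sim["chrom_sizes"].values())
        peak_bp = sum(e - s for _, s, e, _ in truth.planted_peaks)
        expected = 200_000 * peak_bp / genome_len
        observed = sum(
            1
            for c, s, e in mock.fragments
            if any(c == pc and ps <= (s + e) // 2 < pe for pc, ps, pe, _ in truth.planted_peaks)
        )
        assert abs(observed - expected) < 4 * expected**0.5

    def test_low_depth_rejected(self, default_sim):
        with pytest.raises(ValueError, match="depth"):
            simulate_chip(default_sim["annotation"], default_sim["truth"], depth=1000)


class TestSimulateDECounts:
    def test_deterministic(self, default_sim):
        a = simulate_de_counts(default_sim["annotation"], default_sim["truth"], seed=5)
        b = simulate_de_counts(default_sim["annotation"], default_sim["truth"], seed=5)
        assert a.equals(b)

    def test_planted_effect_recovered_at_depth(self, default_sim):
        """Empirical log2FC of activated genes near -effect with deep counts."""
        counts = simulate_de_counts(
            default_sim["annotation"], default_sim["truth"],
            n_cond_reps=4, effect_log2fc=2.0, mean_range=(5000, 5001), seed=3,
        )
        truth = default_sim["truth"]
        wt = counts[[c for c in counts if c.startswith("WT")]].mean(axis=1)
        dl = counts[[c for c in counts if c.startswith("del")]].mean(axis=1)
        lfc = np.log2(dl / wt)
        activated = sorted(truth.direct_activated | truth.indirect_activated)
        assert np.allclose(lfc[activated], -2.0, atol=0.15)
        null = sorted(truth.null_genes)
        assert np.allclose(lfc[null], 0.0, atol=0.15)

    def test_bad_dispersion_rejected(self, default_sim):
        with pytest.raises(ValueError):
            simulate_de_counts(
                default_sim["annotation"], default_sim["truth"], nb_dispersion=0.0
            )


class TestSimulateProteome:
    def test_realized_composition_within_half_point(self, default_sim):
        proteome = default_sim["proteome"]
        truth = default_sim["truth"]
        ranges = {"bin1": (5.0, 9.9), "bin2": (10.1, 12.9)}
        for gid, seq in proteome.items():
            comp = truth.rk_bins_truth[gid]
            pct = rk_fraction(seq)
            if comp in ranges:
                lo, hi = ranges[comp]
                assert lo - 0.5 <= pct <= hi + 0.5

    def test_component_one_gives_all_bin1(self):
        genome, sizes = make_genome(1, 50_000, 0.4, seed=4)
        ann = make_genes(sizes, n_genes=20, seed=4)
        truth = SyntheticTruth(planted_peaks=[], motif_positions=[])
        proteome = simulate_proteome(
            ann, truth, bin_fractions=(1.0, 0.0, 0.0), translation_gene_set=set(), seed=4
        )
        bins = bin_proteome(proteome)
        assert bins.bin_sizes() == {"bin1": 20, "bin2": 0, "bin3": 0}

    def test_realized_bin_shares_track_fractions(self):
        """With a (0.25, 0.50, 0.25) mixture the realized bins mirror the
        genome-wide low/moderate/high split within 3 percentage points."""
        genome, sizes = make_genome(8, 200_000, 0.4, seed=6)
        ann = make_genes(sizes, n_genes=2000, orf_len_range=(150, 250),
                         seed=6, max_attempts=100_000)
        truth = SyntheticTruth(planted_peaks=[], motif_positions=[])
        proteome = simulate_proteome(
            ann, truth, bin_fractions=(0.25, 0.50, 0.25), translation_gene_set=set(), seed=6
        )
        sizes_ = bin_proteome(proteome).bin_sizes()
        n = len(proteome)
        for b, frac in zip(("bin1", "bin2", "bin3"), (0.25, 0.50, 0.25)):
            assert abs(sizes_[b] / n - frac) <= 0.03


def test_simulate_all_deterministic():
    small = dict(n_genes=20, chrom_len=50_000, depth=10_000,
                 n_direct_activated=5, n_direct_repressed=2)
    a = simulate_all(seed=12, **small)
    b = simulate_all(seed=12, **small)
    assert a["genome"] == b["genome"]
    assert a["chip"][0].fragments == b["chip"][0].fragments
    assert a["counts"].equals(b["counts"])
    assert a["proteome"] == b["proteome"]
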