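import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import overlap_groups_quadratic, scan_motif_bruteforce
from nfiomics.chip_integration import (
    annotate_peaks,
    classify_binding,
    motif_enrichment,
    overlap_peaks,
    scan_motif,
    signal_matrix,
    top_targets,
)
from nfiomics.io_formats import GeneModelRecord, GenomicInterval
from nfiomics.synthetic_data import simulate_peaks


def _iv(start, end, chrom="chr1", score=0.0, name=None):
    return GenomicInterval(chrom, start, end, score, name)


def _random_peaksets(rng, n_sets=4, n_peaks=50, span=5000):
    out = {}
    for i in range(n_sets):
        starts = rng.integers(0, span, n_peaks)
        widths = rng.integers(1, 120, n_peaks)
        out[f"S{i}"] = [_iv(int(s), int(s + w)) for s, w in zip(starts, widths)]
    return out


class TestOverlapPeaks:
    def test_single_shared_base_groups(self):
        res = overlap_peaks({"A": [_iv(100, 200)], "B": [_iv(150, 250)]})
        assert res.count("A", "B") == 1 and res.count("A") == 0

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        res = overlap_peaks({"A": [_iv(100, 200)], "B": [_iv(200, 300)]})
        assert res.count("A") == 1 and res.count("B") == 1 and res.count("A", "B") == 0

    def test_identical_sets_only_full_region(self):
        peaks = [_iv(0, 10), _iv(50, 80)]
        res = overlap_peaks({"A": peaks, "B": list(peaks)})
        assert res.region_counts == {frozenset("AB"): 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaksets = _random_peaksets(rng)
        assert overlap_peaks(peaksets).region_counts == overlap_groups_quadratic(peaksets)

    def test_shared_fraction_recovered_from_simulator(self):
        for f in (0.0, 0.3, 1.0):
            peaksets, _, _ = simulate_peaks(4, {"chr1": 80000}, 30, frac_shared=f, seed=2)
            res = overlap_peaks(peaksets)
            assert res.count(*peaksets.keys()) == round(f * 30)


class TestClassifyBinding:
    def test_basic_classes(self):
        a = [_iv(0, 100), _iv(200, 300)]
        b = [_iv(250, 350), _iv(500, 600)]
        res = classify_binding(a, b)
        assert [p.start for p in res["lost"]] == [0]
        assert [p.start for p in res["shared"]] == [200]
        assert [p.start for p in res["gained"]] == [500]

    def test_equal_sets_all_shared(self):
        a = [_iv(0, 10), _iv(20, 30)]
        res = classify_binding(a, list(a))
        assert res["lost"] == [] and res["gained"] == [] and len(res["shared"]) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        sets = _random_peaksets(rng, n_sets=2)
        a, b = sets["S0"], sets["S1"]
        res = classify_binding(a, b)
        assert len(res["lost"]) + len(res["shared"]) == len(a)
        rev = classify_binding(b, a)
        assert {(p.start, p.end) for p in res["lost"]} == {(p.start, p.end) for p in rev["gained"]}


class TestAnnotatePeaks:
    GENES = [
        GeneModelRecord("GENE_B", "chr1", 900, "+"),
        GeneModelRecord("GENE_C", "chr1", 1500, "-"),
        GeneModelRecord("GENE_A", "chr1", 1100, "+"),
    ]

    def test_nearest_tss_wins(self):
        (g,) = annotate_peaks([_iv(950, 1052)], self.GENES)  # center 1001 -> 1100 nearest
        assert g == "GENE_A"

    def test_equidistant_tie_breaks_lexicographically(self):
        (g,) = annotate_peaks([_iv(990, 1010)], self.GENES)  # center 1000: 900 and 1100 tie
        assert g == "GENE_A"

    def test_chromosome_without_genes_unassigned(self):
        (g,) = annotate_peaks([_iv(0, 10, chrom="chrX")], self.GENES)
        assert g is None


class TestTopTargets:
    GENES = [GeneModelRecord(f"G{i}", "chr1", i * 1000, "+") for i in range(10)]

    def test_n_larger_than_peakset_returns_all_genes(self):
        peaks = [_iv(100, 200, score=1), _iv(4100, 4200, score=2)]
        assert top_targets(peaks, self.GENES, n=100) == {"G0", "G4"}

    def test_equal_scores_positional_tie_break_deterministic(self):
        peaks = [_iv(8100, 8200, score=5), _iv(100, 200, score=5), _iv(4100, 4200, score=5)]
        assert top_targets(peaks, self.GENES, n=2) == {"G0", "G4"}

    def test_duplicate_gene_counted_once(self):
        peaks = [_iv(100, 200, score=9), _iv(120, 220, score=8), _iv(4100, 4200, score=1)]
        assert top_targets(peaks, self.GENES, n=2) == {"G0"}


class TestSignalMatrix:
    def test_constant_coverage_flat_matrix(self):
        cov = {"chr1": [(0, 100000, 1.0)]}
        peaks = [_iv(20000, 20200), _iv(50000, 50100)]
        sm = signal_matrix(cov, peaks, window=5000, bin_width=50)
        assert sm.matrix.shape == (2, 200)
        assert np.allclose(sm.matrix, 1.0)
        assert np.allclose(sm.profile, 1.0)

    def test_center_enriched_coverage(self):
        peaks = [_iv(10000, 10200), _iv(30000, 30200)]
        cov = {"chr1": [(p.center - 25, p.center + 25, 10.0) for p in peaks]}
        sm = signal_matrix(cov, peaks, window=1000, bin_width=50)
        for row in sm.matrix:
            center_bin = len(row) // 2
            assert row[center_bin] == max(row) > row[0]

    def test_profile_equals_independent_column_means(self):
        rng = np.random.default_rng(4)
        ivs, pos = [], 0
        for _ in range(300):
            width = int(rng.integers(10, 80))
            ivs.append((pos, pos + width, float(rng.random() * 5)))
            pos += width
        cov = {"chr1": ivs}
        peaks = [_iv(int(s), int(s) + 100) for s in rng.integers(2000, pos - 2000, 10)]
        sm = signal_matrix(cov, peaks, window=1000, bin_width=100)
        assert np.allclose(sm.profile, sm.matrix.mean(axis=0))

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            signal_matrix({}, [], window=100, bin_width=33)

    def test_reference_order_respected(self):
        cov = {"chr1": [(0, 100000, 1.0)]}
        peaks = [_iv(10000, 10100), _iv(20000, 20100), _iv(30000, 30100)]
        sm = signal_matrix(cov, peaks, window=500, bin_width=50, reference_order=[2, 0, 1])
        assert [p.start for p in sm.peaks] == [30000, 10000, 20000]

    def test_binned_mean_against_direct_base_average(self):
        # one irregular step function, bin means recomputed base by base
        ivs = [(0, 30, 2.0), (30, 45, 0.5), (60, 100, 4.0)]
        base = np.zeros(200)
        for s, e, v in ivs:
            base[s:e] = v
        peak = _iv(40, 60)  # center 50
        sm = signal_matrix({"chr1": ivs}, [peak], window=50, bin_width=10)
        direct = base[0:100].reshape(10, 10).mean(axis=1)
        assert np.allclose(sm.matrix[0], direct)


class TestScanMotif:
    def test_planted_canonical_site(self):
        hits = scan_motif({"chr1": "AATTGGCACGTAGCCAATT"})
        exact = [h for h in hits if h.n_mismatches == 0]
        assert any(h.start == 2 and h.spacer_len == 5 for h in exact)

    def test_short_spacer(self):
        hits = scan_motif({"chr1": "TTGGCAAAGCCAA"})
        assert any(h.start == 0 and h.spacer_len == 3 and h.n_mismatches == 0 for h in hits)

    def test_n_never_matches(self):
        hits = scan_motif({"chr1": "TTGGCNNNNNGCCAA"}, max_mismatch_per_half=0)
        assert [h for h in hits if h.n_mismatches == 0 and h.spacer_len == 5]
        none = scan_motif({"chr1": "NTGGCAAAAAGCCAA"}, max_mismatch_per_half=0)
        assert not [h for h in none if h.spacer_len == 5 and h.start == 0]

    def test_minus_strand_found_and_duplicates_merged(self):
        # motif with 0 mismatches is its own reverse complement: one merged '+' hit
        hits = scan_motif({"chr1": "TTGGCACGTAGCCAA"})
        at_zero = [h for h in hits if h.start == 0 and h.spacer_len == 5]
        assert len(at_zero) == 1 and at_zero[0].strand == "+"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20000))}
        mine = {(h.chrom, h.start, h.spacer_len): h.strand for h in scan_motif(genome)}
        assert mine == scan_motif_bruteforce(genome)


class TestMotifEnrichment:
    def test_planted_everywhere_gives_minimal_p(self):
        peaksets, genome, _ = simulate_peaks(1, {"chr1": 30000}, 15, 0.0, seed=1)
        res = motif_enrichment(peaksets["NFIA"], genome, n_shuffles=19, seed=0,
                               max_mismatch_per_half=0)
        assert res["fraction_with_hit"] == 1.0

    def test_motif_free_genome_zero_fraction(self):
        genome = {"chr1": "A" * 5000}
        peaks = [_iv(100, 300), _iv(1000, 1200)]
        res = motif_enrichment(peaks, genome, n_shuffles=10, seed=0)
        assert res["fraction_with_hit"] == 0.0

    def test_deterministic_under_seed(self):
        peaksets, genome, _ = simulate_peaks(1, {"chr1": 20000}, 10, 0.0, seed=3)
        r1 = motif_enrichment(peaksets["NFIA"], genome, n_shuffles=25, seed=7)
        r2 = motif_enrichment(peaksets["NFIA"], genome, n_shuffles=25, seed=7)
        assert r1 == r2
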