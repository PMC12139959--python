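"""Signature-scan tests: frozen geometric examples, dual-route z-score,
brute-force oracle equivalence, bias and size summaries."""

import math

import numpy as np
import pytest

from srnasig import (
    AlignedRead,
    Library,
    dicer_pair_fraction,
    first_nt_bias,
    overlap_histogram,
    phasing_histogram,
    signature_zscore,
    size_distribution,
)
from srnasig.scenarios import planted_signal_library, random_library
from srnasig.simulate import PlantedLocusSpec, SimConfig, simulate_library

from _oracles import oracle_dicer_percent, oracle_overlap_counts, oracle_phasing_counts


def read(chrom="chr1", strand="+", start=100, end=121, first_nt="N"):
    return AlignedRead(chrom=chrom, strand=strand, start=start, end=end, first_nt=first_nt)


class TestDicerPairFraction:
    def test_single_qualifying_pair_is_100_percent(self, dicer_pair_library):
        assert dicer_pair_fraction(dicer_pair_library) == 100.0

    def test_single_strand_library_has_no_pairs(self):
        lib = Library(reads=[read(start=s, end=s + 21) for s in range(0, 200, 40)])
        assert dicer_pair_fraction(lib) == 0.0

    def test_length_window_excludes_out_of_range_duplex(self):
        # perfect 2-nt overhang geometry but 28-nt reads: not Dicer-sized
        lib = Library(reads=[read(start=100, end=128), read(strand="-", start=98, end=126)])
        assert dicer_pair_fraction(lib) == 0.0

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            dicer_pair_fraction(Library(reads=[]))

    def test_one_end_matching_flag_relaxes_the_predicate(self):
        # 5' boundaries offset by 2 but 3' boundaries not: only one end matches
        lib = Library(reads=[read(start=100, end=121), read(strand="-", start=98, end=120)])
        assert dicer_pair_fraction(lib) == 0.0
        assert dicer_pair_fraction(lib, both_ends=False) == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        lib = random_library(seed, n_reads=500, chrom_length=10_000, length_range=(18, 26))
        assert dicer_pair_fraction(lib) == oracle_dicer_percent(lib)


class TestOverlapHistogram:
    def test_ten_nt_overlap_pair(self):
        lib = Library(reads=[read(start=100, end=128), read(strand="-", start=82, end=110)])
        hist = overlap_histogram(lib)
        assert hist.counts[10] == 1
        assert sum(hist.counts.values()) == 1

    def test_single_strand_gives_empty_histogram(self):
        lib = Library(reads=[read(start=s, end=s + 28) for s in range(0, 280, 28)])
        assert sum(overlap_histogram(lib).counts.values()) == 0

    def test_planted_pingpong_pairs_match_manifest(self):
        lib, man = planted_signal_library(21, "pingpong_pirna", n_signal=400)
        expected = sum(t.expected["pingpong_pairs_at_10"] for t in man.loci)
        assert overlap_histogram(lib).counts[10] == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        lib = random_library(100 + seed, n_reads=600, chrom_length=8_000)
        assert overlap_histogram(lib).counts == oracle_overlap_counts(lib)


class TestSignatureZscore:
    def test_flat_histogram_scores_zero(self):
        assert signature_zscore({b: 5 for b in range(1, 21)}, focal=10) == 0.0

    def test_zero_sd_elevated_focal_hits_the_cap(self):
        counts = {b: 10 for b in range(1, 21)}
        counts[10] = 40
        assert signature_zscore(counts, focal=10) == 10.0
        assert signature_zscore(counts, focal=10, cap=5.0) == 5.0

    def test_zero_sd_depressed_focal_hits_negative_cap(self):
        counts = {b: 10 for b in range(1, 21)}
        counts[10] = 0
        assert signature_zscore(counts, focal=10) == -10.0

    def test_too_few_background_bins_rejected(self):
        with pytest.raises(ValueError):
            signature_zscore({1: 3, 2: 4, 3: 5}, focal=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        counts = {b: int(c) for b, c in enumerate(rng.integers(0, 50, size=30), start=1)}
        bg = np.array([c for b, c in counts.items() if b != 10], dtype=float)
        expected = (counts[10] - bg.mean()) / bg.std()
        assert signature_zscore(counts, focal=10) == pytest.approx(expected, abs=1e-12)


class TestPhasingHistogram:
    def test_head_to_tail_adjacency_counts_at_one(self):
        lib = Library(reads=[read(start=100, end=128, first_nt="U"),
                             read(start=128, end=156, first_nt="U")])
        assert phasing_histogram(lib).counts[1] == 1

    def test_non_u_downstream_read_excluded(self):
        lib = Library(reads=[read(start=100, end=128, first_nt="U"),
                             read(start=128, end=156, first_nt="A")])
        assert sum(phasing_histogram(lib).counts.values()) == 0

    def test_minus_strand_downstream_is_leftward(self):
        # transcript runs right-to-left: [128,156) upstream, [100,128) next
        lib = Library(reads=[read(strand="-", start=128, end=156, first_nt="U"),
                             read(strand="-", start=100, end=128, first_nt="U")])
        assert phasing_histogram(lib).counts[1] == 1

    def test_planted_trail_gives_k_minus_one_adjacencies(self):
        cfg = SimConfig(
            chrom_length=10_000, seed=2,
            loci_specs=[PlantedLocusSpec("phased_pirna", "chr1", 100, 20,
                                         length_range=(28, 28), u1_prob=1.0)],
        )
        lib, _, _ = simulate_library(cfg)
        assert phasing_histogram(lib).counts[1] == 19

    @pytest.mark.parametrize("pairing", ["all", "nearest"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed, pairing):
        lib = random_library(200 + seed, n_reads=600, chrom_length=8_000)
        got = phasing_histogram(lib, pairing=pairing).counts
        assert got == oracle_phasing_counts(lib, pairing=pairing)


class TestFirstNtBias:
    def test_all_u_reads(self):
        lib = Library(reads=[read(first_nt="U"), read(start=200, end=228, first_nt="U")])
        assert first_nt_bias(lib) == 1.0

    def test_short_reads_leave_the_denominator(self):
        reads = [read(start=0, end=16, first_nt="U"), read(start=50, end=78, first_nt="U")]
        cfg = SimConfig(chrom_length=1000, seed=0)
        from srnasig.simulate import generate_genome

        genome = generate_genome(cfg)
        # only the 28-mer reaches position 20
        frac = first_nt_bias(reads, position=20, genome=genome)
        assert frac in (0.0, 1.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            first_nt_bias([])

    def test_simulated_u1_prob_recovered_within_binomial_error(self):
        cfg = SimConfig(
            chrom_length=50_000, seed=3,
            loci_specs=[PlantedLocusSpec("phased_pirna", "chr1", 100, 1000,
                                         length_range=(26, 26), u1_prob=0.8)],
        )
        lib, _, _ = simulate_library(cfg)
        se = math.sqrt(0.8 * 0.2 / 1000)
        assert abs(first_nt_bias(lib) - 0.8) <= 3 * se


class TestSizeDistribution:
    def test_dicer_band_counts(self):
        lib = Library(reads=[read(start=0, end=22) for _ in range(10)])
        hist = size_distribution(lib)
        assert hist.dicer_products == 10
        assert hist.pirna == 0 and hist.degradation == 0

    def test_empty_set_is_all_zero(self):
        hist = size_distribution([])
        assert hist.total == 0
        assert hist.band_fractions() == {"degradation": 0.0, "dicer_products": 0.0, "pirna": 0.0}

    def test_length_25_belongs_to_no_band(self):
        hist = size_distribution([read(start=0, end=25)])
        assert hist.total == 1
        assert hist.degradation + hist.dicer_products + hist.pirna == 0

    def test_band_totals_match_manifest_classes(self, mixed_sim):
        lib, man = mixed_sim
        hist = size_distribution(lib)
        pirna_truth = sum(
            t.n_reads for t in man.loci if t.class_label in ("pingpong_pirna", "phased_pirna")
        )
        deg_truth = sum(t.n_reads for t in man.loci if t.class_label == "degradation")
        assert hist.pirna == pirna_truth
        assert hist.degradation == deg_truth
        assert hist.total == lib.total_alignments
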