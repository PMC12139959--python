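"""Locus annotation: coverage calling vs a per-base oracle, merge
semantics, RPM boundary behaviour, sweep monotonicity and genome fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnasig import (
    AlignedRead,
    Library,
    Region,
    annotate_loci,
    call_regions,
    genome_fraction,
    merge_regions,
    rpm_filter,
    threshold_sweep,
)
from srnasig.loci import Locus, build_loci, MERGE_GRID, RPM_GRID
from srnasig.scenarios import random_library
from srnasig.simulate import PlantedLocusSpec, SimConfig, simulate_library


def read(start, end, chrom="chr1", strand="+"):
    return AlignedRead(chrom=chrom, strand=strand, start=start, end=end)


def coverage_oracle(library, min_cov=1):
    """Direct per-base coverage array scan."""
    regions = []
    for chrom in sorted(library.chroms):
        reads = [r for r in library if r.chrom == chrom]
        hi = max(r.end for r in reads)
        cov = np.zeros(hi, dtype=int)
        for r in reads:
            cov[r.start : r.end] += 1
        inside = False
        for pos in range(hi + 1):
            covered = pos < hi and cov[pos] >= min_cov
            if covered and not inside:
                start, inside = pos, True
            elif not covered and inside:
                regions.append(Region(chrom, start, pos))
                inside = False
    return regions


class TestCallRegions:
    def test_single_read_single_region(self):
        lib = Library(reads=[read(100, 128)])
        assert call_regions(lib) == [Region("chr1", 100, 128)]

    def test_gap_splits_regions(self):
        lib = Library(reads=[read(100, 128), read(200, 228)])
        assert call_regions(lib) == [Region("chr1", 100, 128), Region("chr1", 200, 228)]

    def test_strand_pooling_merges_opposite_strand_coverage(self):
        lib = Library(reads=[read(100, 128), read(110, 138, strand="-")])
        assert call_regions(lib) == [Region("chr1", 100, 138)]
        assert len(call_regions(lib, per_strand=True)) == 2

    def test_min_cov_thresholds_depth(self):
        lib = Library(reads=[read(100, 130), read(120, 150)])
        assert call_regions(lib, min_cov=2) == [Region("chr1", 120, 130)]

    def test_empty_library_empty_regions(self):
        assert call_regions(Library(reads=[])) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_base_coverage_oracle(self, seed):
        lib = random_library(300 + seed, n_reads=400, chrom_length=5_000, n_chroms=2)
        for min_cov in (1, 2, 3):
            assert call_regions(lib, min_cov=min_cov) == coverage_oracle(lib, min_cov)


regions_strategy = st.lists(
    st.tuples(st.integers(0, 5), st.integers(0, 10_000), st.integers(1, 500)),
    min_size=0,
    max_size=40,
).map(lambda triples: [Region(f"chr{c}", s, s + l) for c, s, l in triples])


class TestMergeRegions:
    def test_gap_at_distance_is_inclusive(self):
        merged = merge_regions([Region("chr1", 0, 100), Region("chr1", 550, 600)], 500)
        assert merged == [Region("chr1", 0, 600)]

    def test_gap_beyond_distance_not_merged(self):
        regions = [Region("chr1", 0, 100), Region("chr1", 601, 700)]
        assert len(merge_regions(regions, 500)) == 2

    def test_distance_zero_unites_only_touching(self):
        regions = [Region("chr1", 0, 100), Region("chr1", 100, 150), Region("chr1", 152, 200)]
        merged = merge_regions(regions, 0)
        assert merged == [Region("chr1", 0, 150), Region("chr1", 152, 200)]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            merge_regions([], -1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(regions=regions_strategy, dist=st.integers(0, 2000))
    def test_idempotent_sorted_disjoint(self, regions, dist):
        once = merge_regions(regions, dist)
        assert merge_regions(once, dist) == once
        for a, b in zip(once, once[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            if a.chrom == b.chrom:
                assert b.start - a.end > dist


class TestRpmFilter:
    def test_below_threshold_removed(self):
        loci = [Locus("chr1", 0, 100, read_count=10, rpm=10.0)]
        assert rpm_filter(loci, 1_000_000, 1000.0) == []

    def test_exact_boundary_kept(self):
        loci = [Locus("chr1", 0, 100, read_count=1000, rpm=1000.0)]
        assert rpm_filter(loci, 1_000_000, 1000.0) == loci

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_filter([], 0)

    def test_matches_direct_filter(self):
        rng = np.random.default_rng(1)
        loci = [
            Locus("chr1", i * 100, i * 100 + 50, read_count=int(c), rpm=float(c) / 5e5 * 1e6)
            for i, c in enumerate(rng.integers(0, 2000, size=50))
        ]
        got = rpm_filter(loci, 500_000, 1000.0)
        assert got == [l for l in loci if l.rpm >= 1000.0]


@pytest.fixture(scope="module")
def planted_pair_450bp_apart():
    # phased trails are contiguous blocks: [1000,1280) and [1730,2010),
    # a 450-bp gap between the planted loci
    cfg = SimConfig(
        chrom_length=10_000, seed=5,
        loci_specs=[
            PlantedLocusSpec("phased_pirna", "chr1", 1000, 10, length_range=(28, 28)),
            PlantedLocusSpec("phased_pirna", "chr1", 1730, 10, length_range=(28, 28)),
        ],
    )
    lib, _, _ = simulate_library(cfg)
    return lib


class TestThresholdSweep:
    def test_two_loci_450bp_apart_merge_only_at_500_or_more(self, planted_pair_450bp_apart):
        lib = planted_pair_450bp_apart
        sweep = threshold_sweep(lib, {"chr1": 10_000}, MERGE_GRID, (0,))
        n_by_merge = dict(zip(sweep["merge_distance"], sweep["n_loci"]))
        assert n_by_merge[0] == n_by_merge[5] == n_by_merge[50] == 2
        assert n_by_merge[500] == n_by_merge[5000] == n_by_merge[50000] == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_monotonicity_over_random_libraries(self, seed):
        lib = random_library(400 + seed, n_reads=2000, chrom_length=50_000)
        sweep = threshold_sweep(lib, {"chr1": 50_000})
        for md, cell in sweep.groupby("merge_distance"):
            cell = cell.sort_values("min_rpm")
            assert (np.diff(cell["n_loci"]) <= 0).all()
            assert (np.diff(cell["genome_fraction_pct"]) <= 1e-12).all()
        for rpm, cell in sweep.groupby("min_rpm"):
            cell = cell.sort_values("merge_distance")
            assert (np.diff(cell["genome_fraction_pct"]) >= -1e-12).all()

    def test_empty_grids_rejected(self):
        lib = random_library(1, n_reads=100)
        with pytest.raises(ValueError):
            threshold_sweep(lib, {"chr1": 10_000}, (), ())


class TestGenomeFraction:
    def test_single_locus_fraction(self):
        loci = [Locus("chr1", 0, 360)]
        assert genome_fraction(loci, {"chr1": 100_000}) == pytest.approx(0.36)

    def test_no_loci_zero(self):
        assert genome_fraction([], {"chr1": 1000}) == 0.0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            genome_fraction([], {})

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        loci, pos = [], 0
        for _ in range(30):
            pos += int(rng.integers(1, 500))
            loci.append(Locus("chr1", pos, pos + int(rng.integers(1, 300))))
            pos = loci[-1].end
        glens = {"chr1": 50_000, "chr2": 25_000}
        expected = 100.0 * sum(l.end - l.start for l in loci) / 75_000
        assert genome_fraction(loci, glens) == pytest.approx(expected, abs=1e-12)


class TestAnnotateLoci:
    def test_planted_locus_recovered_with_counts(self):
        cfg = SimConfig(
            chrom_length=10_000, seed=8,
            loci_specs=[PlantedLocusSpec("pingpong_pirna", "chr1", 2000, 200, span=100)],
        )
        lib, man, _ = simulate_library(cfg)
        loci = annotate_loci(lib, merge_distance=500, min_rpm=1000.0)
        assert len(loci) == 1
        truth = man.loci[0]
        assert loci[0].start <= truth.start and loci[0].end >= truth.end
        assert loci[0].read_count == truth.n_reads

    def test_read_count_conservation_by_five_prime_containment(self, mixed_sim):
        lib, _ = mixed_sim
        loci = build_loci(merge_regions(call_regions(lib), 500), lib)
        # every read's 5' end lies in some coverage region, so counts conserve
        assert sum(l.read_count for l in loci) == lib.total_alignments
        assert loci == sorted(loci, key=lambda l: (l.chrom, l.start))
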