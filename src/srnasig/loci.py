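"""Annotation of small-RNA-expressing loci.

Loci are called as maximal intervals of strand-pooled per-base alignment
coverage, merged when their gap is within a merge distance, and filtered
by RPM depth.  The operating point used throughout (merge within 500 bp,
keep loci >= 1000 RPM) is chosen by a grid sweep over merge distances
{0, 5, 50, 500, 5000, 50000} bp crossed with RPM depth thresholds from 0
to one million, trading locus count against genome fraction.

Reads are assigned to loci by 5'-end containment: a read belongs to the
locus containing its 5' coordinate, which keeps boundary-straddling reads
unambiguous.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Library

MERGE_GRID = (0, 5, 50, 500, 5000, 50000)
RPM_GRID = (0, 1, 10, 100, 1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True, slots=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Locus:
    """A small-RNA-expressing locus with its depth and annotations."""

    chrom: str
    start: int
    end: int
    read_count: int = 0
    rpm: float = 0.0
    locus_id: str = ""
    size_profile: dict | None = None
    pingpong_z: float | None = None
    phasing_z: float | None = None
    class_label: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end)


def _sort_regions(regions) -> list[Region]:
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))


def call_regions(library: Library, min_cov: int = 1, per_strand: bool = False) -> list[Region]:
    """Maximal intervals where per-base alignment coverage >= ``min_cov``.

    Coverage is pooled across strands by default (loci are strand-agnostic
    features); ``per_strand=True`` calls plus and minus separately and
    returns the union of both strands' regions re-sorted.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    groups: dict[tuple, list] = defaultdict(list)
    for r in library:
        key = (r.chrom, r.strand) if per_strand else (r.chrom,)
        groups[key].append(r)
    regions: list[Region] = []
    for key in sorted(groups):
        chrom = key[0]
        reads = groups[key]
        hi = max(r.end for r in reads)
        diff = np.zeros(hi + 1, dtype=np.int64)
        for r in reads:
            diff[r.start] += 1
            diff[r.end] -= 1
        cov = np.cumsum(diff) >= min_cov
        # run boundaries of the boolean coverage mask
        edges = np.flatnonzero(np.diff(np.concatenate(([False], cov, [False]))))
        for s, e in zip(edges[0::2], edges[1::2]):
            regions.append(Region(chrom, int(s), int(e)))
    return _sort_regions(regions)


def merge_regions(regions, merge_distance: int) -> list[Region]:
    """Unite regions whose gap (next.start - prev.end) <= merge_distance.

    Idempotent; result sorted and pairwise disjoint.  merge_distance 0
    unites only touching/overlapping regions.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    regions = _sort_regions(regions)
    merged: list[Region] = []
    for reg in regions:
        if merged and merged[-1].chrom == reg.chrom and reg.start - merged[-1].end <= merge_distance:
            prev = merged[-1]
            merged[-1] = Region(prev.chrom, prev.start, max(prev.end, reg.end))
        else:
            merged.append(reg)
    return merged


def assign_read_counts(regions, library: Library) -> list[int]:
    """Reads per region by 5'-end containment (regions must be disjoint)."""
    starts_by_chrom: dict[str, list[int]] = defaultdict(list)
    ends_by_chrom: dict[str, list[int]] = defaultdict(list)
    idx_by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, reg in enumerate(regions):
        starts_by_chrom[reg.chrom].append(reg.start)
        ends_by_chrom[reg.chrom].append(reg.end)
        idx_by_chrom[reg.chrom].append(i)
    counts = [0] * len(regions)
    for r in library:
        starts = starts_by_chrom.get(r.chrom)
        if not starts:
            continue
        j = bisect_right(starts, r.five_prime) - 1
        if j >= 0 and r.five_prime < ends_by_chrom[r.chrom][j]:
            counts[idx_by_chrom[r.chrom][j]] += 1
    return counts


def build_loci(regions, library: Library) -> list[Locus]:
    """Turn disjoint regions into loci with read counts and RPM."""
    total = library.total_alignments
    if total == 0:
        raise ValueError("cannot compute RPM for an empty library")
    counts = assign_read_counts(regions, library)
    return [
        Locus(
            chrom=reg.chrom,
            start=reg.start,
            end=reg.end,
            read_count=c,
            rpm=c / total * 1e6,
            locus_id=f"locus_{i + 1:05d}",
        )
        for i, (reg, c) in enumerate(zip(regions, counts))
    ]


def rpm_filter(loci, total_alignments: int, min_rpm: float = 1000.0) -> list[Locus]:
    """Keep loci with RPM >= min_rpm (inclusive boundary)."""
    if total_alignments <= 0:
        raise ValueError("total_alignments must be positive")
    return [l for l in loci if l.rpm >= min_rpm]


def annotate_loci(
    library: Library,
    merge_distance: int = 500,
    min_rpm: float = 1000.0,
    min_cov: int = 1,
) -> list[Locus]:
    """Full annotation pass: call coverage regions, merge, count, RPM-filter."""
    if library.total_alignments == 0:
        return []
    regions = merge_regions(call_regions(library, min_cov=min_cov), merge_distance)
    loci = build_loci(regions, library)
    kept = rpm_filter(loci, library.total_alignments, min_rpm)
    for i, loc in enumerate(kept):
        loc.locus_id = f"locus_{i + 1:05d}"
    return kept


def genome_fraction(loci, genome_lengths: dict[str, int]) -> float:
    """Percent of the genome covered by the loci."""
    if not genome_lengths:
        raise ValueError("empty genome length table")
    genome_total = sum(genome_lengths.values())
    covered = sum(l.length for l in loci)
    return 100.0 * covered / genome_total


def threshold_sweep(
    library: Library,
    genome_lengths: dict[str, int],
    merge_grid=MERGE_GRID,
    rpm_grid=RPM_GRID,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Evaluate the merge-distance x RPM-depth grid.

    One coverage pass is reused across the whole grid.  Returns a tidy
    frame with columns merge_distance, min_rpm, n_loci,
    genome_fraction_pct.
    """
    if not merge_grid or not rpm_grid:
        raise ValueError("merge and rpm grids must be non-empty")
    base = call_regions(library, min_cov=min_cov)
    rows = []
    for md in merge_grid:
        loci = build_loci(merge_regions(base, md), library)
        for min_rpm in rpm_grid:
            kept = [l for l in loci if l.rpm >= min_rpm]
            rows.append(
                {
                    "merge_distance": md,
                    "min_rpm": min_rpm,
                    "n_loci": len(kept),
                    "genome_fraction_pct": genome_fraction(kept, genome_lengths),
                }
            )
    return pd.DataFrame(rows)
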