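"""Read-geometry signatures of small-RNA biogenesis.

Three statistics diagnose how a small-RNA population was made:

* **Dicer-pair percent** — RNase III enzymes cut duplexes leaving 2-nt 3'
  overhangs at both ends, so endogenous siRNA production shows up as
  opposite-strand 20-24 nt read pairs offset by exactly 2 nt at both
  boundaries.  The percent is the fraction of alignments that belong to at
  least one such qualifying pair (membership, not pair count, keeps the
  ratio <= 100%).
* **Ping-Pong signature** — the piRNA amplification loop produces
  opposite-strand pairs whose 5' ends overlap by exactly 10 nt; an
  enrichment at overlap 10 over neighbouring overlaps (summarised by a
  z-score) marks Ping-Pong activity.
* **Phasing signature** — Zucchini/mito-PLD cleavage lays 1U piRNAs
  head-to-tail, so the distance from an upstream alignment's 3' end to the
  next 1U read's 5' end concentrates at 1.

The z-score for a histogram compares the focal bin against all other bins
in range (population sd); a zero-sd background with a deviating focal bin
is reported as a capped +/-10 rather than infinity.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AlignedRead,
    Library,
    DEGRADATION_BAND,
    DICER_BAND,
    PIRNA_BAND,
    MIN_READ_LEN,
    MAX_READ_LEN,
)

Z_CAP = 10.0


def signature_zscore(counts: dict[int, int] | "np.ndarray", focal: int, cap: float = Z_CAP) -> float:
    """Focal-bin z-score against the non-focal background bins.

    ``counts`` maps bin -> count over the full histogram range.  Background
    mean/sd use the population (n) denominator.  If the background sd is 0
    the score is 0 when the focal bin equals the mean and ``+/-cap``
    otherwise.  Requires at least 3 background bins.
    """
    if isinstance(counts, np.ndarray):
        counts = {i + 1: int(c) for i, c in enumerate(counts)}
    if focal not in counts:
        raise ValueError(f"focal bin {focal} outside histogram range")
    background = np.array([c for b, c in counts.items() if b != focal], dtype=float)
    if background.size < 3:
        raise ValueError("need at least 3 background bins for a z-score")
    mean = background.mean()
    sd = background.std()  # population sd
    focal_count = counts[focal]
    if sd == 0.0:
        if focal_count == mean:
            return 0.0
        return cap if focal_count > mean else -cap
    return float((focal_count - mean) / sd)


@dataclass
class OverlapHistogram:
    """Counts of 5'-5' overlap lengths between opposite-strand read pairs."""

    counts: dict[int, int]
    focal: int = 10
    z: float = field(init=False)

    def __post_init__(self) -> None:
        self.z = signature_zscore(self.counts, self.focal)

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhasingHistogram:
    """Counts of distances from an upstream alignment's end to the 5' start
    of the nearest downstream 1U read (head-to-tail adjacency gives d=1)."""

    counts: dict[int, int]
    focal: int = 1
    z: float = field(init=False)

    def __post_init__(self) -> None:
        self.z = signature_zscore(self.counts, self.focal)


@dataclass
class SizeHistogram:
    """Read counts per length with the three biogenesis bands."""

    counts: dict[int, int]

    def _band(self, band: tuple[int, int]) -> int:
        lo, hi = band
        return sum(c for length, c in self.counts.items() if lo <= length <= hi)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def degradation(self) -> int:
        return self._band(DEGRADATION_BAND)

    @property
    def dicer_products(self) -> int:
        return self._band(DICER_BAND)

    @property
    def pirna(self) -> int:
        return self._band(PIRNA_BAND)

    def band_fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"degradation": 0.0, "dicer_products": 0.0, "pirna": 0.0}
        return {
            "degradation": self.degradation / t,
            "dicer_products": self.dicer_products / t,
            "pirna": self.pirna / t,
        }


def _iter_reads(reads) -> list[AlignedRead]:
    return list(reads.reads) if isinstance(reads, Library) else list(reads)


def dicer_pair_fraction(
    library: Library,
    pair_min_len: int = 20,
    pair_max_len: int = 24,
    overhang: int = 2,
    both_ends: bool = True,
) -> float:
    """Percent of alignments that belong to >=1 qualifying Dicer pair.

    A qualifying pair is a plus read *p* and a minus read *m* on the same
    chromosome, both within the Dicer length window, with
    ``p.start - m.start == overhang`` and ``p.end - m.end == overhang``
    (2-nt 3' overhangs at both duplex ends, which forces equal lengths).
    With ``both_ends=False`` one matching boundary suffices.

    Raises on an empty library (the percent is undefined).
    """
    reads = _iter_reads(library)
    total = library.total_alignments if isinstance(library, Library) else len(reads)
    if total == 0:
        raise ValueError("Dicer-pair percent is undefined for an empty library")
    in_window = [r for r in reads if pair_min_len <= r.length <= pair_max_len]
    plus = [r for r in in_window if r.strand == "+"]
    minus = [r for r in in_window if r.strand == "-"]
    if both_ends:
        minus_keys = {(r.chrom, r.start, r.end) for r in minus}
        plus_keys = {(r.chrom, r.start, r.end) for r in plus}
        n_members = sum(
            1 for r in plus if (r.chrom, r.start - overhang, r.end - overhang) in minus_keys
        )
        n_members += sum(
            1 for r in minus if (r.chrom, r.start + overhang, r.end + overhang) in plus_keys
        )
    else:
        minus_starts = {(r.chrom, r.start) for r in minus}
        minus_ends = {(r.chrom, r.end) for r in minus}
        plus_starts = {(r.chrom, r.start) for r in plus}
        plus_ends = {(r.chrom, r.end) for r in plus}
        n_members = sum(
            1
            for r in plus
            if (r.chrom, r.start - overhang) in minus_starts or (r.chrom, r.end - overhang) in minus_ends
        )
        n_members += sum(
            1
            for r in minus
            if (r.chrom, r.start + overhang) in plus_starts or (r.chrom, r.end + overhang) in plus_ends
        )
    return 100.0 * n_members / total


def overlap_histogram(library, max_overlap: int = 30, focal: int = 10) -> OverlapHistogram:
    """Histogram of 5'-5' overlaps between opposite-strand read pairs.

    For a plus read *p* and minus read *m* on the same chromosome the
    overlap is ``o = m.five_prime - p.five_prime + 1``; each pair with
    ``1 <= o <= max_overlap`` counts once.
    """
    reads = _iter_reads(library)
    plus5: dict[str, Counter] = defaultdict(Counter)
    minus5: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        (plus5 if r.strand == "+" else minus5)[r.chrom][r.five_prime] += 1
    counts = {o: 0 for o in range(1, max_overlap + 1)}
    for chrom, pcounter in plus5.items():
        mcounter = minus5.get(chrom)
        if not mcounter:
            continue
        for p5, n_p in pcounter.items():
            for o in range(1, max_overlap + 1):
                n_m = mcounter.get(p5 + o - 1, 0)
                if n_m:
                    counts[o] += n_p * n_m
    return OverlapHistogram(counts=counts, focal=focal)


def phasing_histogram(
    library, max_dist: int = 20, focal: int = 1, pairing: str = "all"
) -> PhasingHistogram:
    """Histogram of 1U-read distances to upstream alignments.

    Same strand, same chromosome; for a downstream 1U read *w* and an
    upstream alignment *u* the distance is ``d = w.start - u.end + 1`` on
    plus (``u.start - w.end + 1`` on minus, where downstream means
    leftward), so head-to-tail adjacency gives ``d = 1``.

    ``pairing='all'`` (default) counts every upstream alignment within
    range, as the established phasing spectrum does; its null expectation
    is flat in *d* for uniformly placed reads.  ``pairing='nearest'``
    pairs each downstream read with its nearest upstream alignment only
    (at most one count per read), which damps deep stacks but has a
    slightly decreasing null expectation in *d*.  ``max_dist`` defaults to
    20 so the focal z-score has a well-populated background; figures
    customarily display distances 1-9.
    """
    if pairing not in ("all", "nearest"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    reads = _iter_reads(library)
    by_group: dict[tuple[str, str], list[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_group[(r.chrom, r.strand)].append(r)
    counts = {d: 0 for d in range(1, max_dist + 1)}
    for (_, strand), group in by_group.items():
        if strand == "+":
            # upstream ends to the left: candidate 3' ends <= w.start
            ends = sorted(r.end for r in group)
            for w in group:
                if w.first_nt != "U":
                    continue
                i = bisect_right(ends, w.start)
                if pairing == "nearest":
                    if i == 0:
                        continue
                    d = w.start - ends[i - 1] + 1
                    if 1 <= d <= max_dist:
                        counts[d] += 1
                else:
                    j = bisect_left(ends, w.start - max_dist + 1)
                    for e in ends[j:i]:
                        counts[w.start - e + 1] += 1
        else:
            # on minus the transcript runs right-to-left: upstream is to the
            # right, its 3' end is the genomic start
            starts = sorted(r.start for r in group)
            for w in group:
                if w.first_nt != "U":
                    continue
                i = bisect_left(starts, w.end)
                if pairing == "nearest":
                    if i == len(starts):
                        continue
                    d = starts[i] - w.end + 1
                    if 1 <= d <= max_dist:
                        counts[d] += 1
                else:
                    j = bisect_right(starts, w.end + max_dist - 1)
                    for s in starts[i:j]:
                        counts[s - w.end + 1] += 1
    return PhasingHistogram(counts=counts, focal=focal)


def first_nt_bias(reads, position: int = 1, nucleotide: str = "U", genome=None) -> float:
    """Fraction of reads whose nucleotide at a 1-based 5' position matches.

    Position 1 uses the stored first nucleotide; deeper positions need the
    genome (chrom -> sequence).  Reads shorter than ``position`` leave the
    denominator.  Raises on an empty read set.
    """
    reads = _iter_reads(reads)
    if not reads:
        raise ValueError("first-nt bias is undefined for an empty read set")
    if position < 1:
        raise ValueError("position is 1-based")
    eligible = [r for r in reads if r.length >= position]
    if not eligible:
        raise ValueError(f"no reads reach position {position}")
    if position == 1:
        hits = sum(1 for r in eligible if r.first_nt == nucleotide)
        return hits / len(eligible)
    if genome is None:
        raise ValueError("positions beyond 1 require the genome sequence")
    from .model import COMPLEMENT, to_rna

    hits = 0
    for r in eligible:
        seq = genome[r.chrom]
        if r.strand == "+":
            base = str(seq[r.start + position - 1])
        else:
            base = COMPLEMENT[str(seq[r.end - position])]
        if to_rna(base) == nucleotide:
            hits += 1
    return hits / len(eligible)


def size_distribution(reads) -> SizeHistogram:
    """Per-length read counts over the screened range (15-30 nt)."""
    reads = _iter_reads(reads)
    counts = {length: 0 for length in range(MIN_READ_LEN, MAX_READ_LEN + 1)}
    for r in reads:
        counts[r.length] = counts.get(r.length, 0) + 1
    return SizeHistogram(counts=counts)
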