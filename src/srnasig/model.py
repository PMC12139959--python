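"""Core in-memory model: aligned small-RNA reads and libraries.

Coordinates are 0-based, half-open everywhere inside the package; SAM's
1-based closed convention is converted at the I/O boundary.  A read's 5'
end is its ``start`` on the plus strand and ``end - 1`` on the minus
strand.  First-nucleotide identity is reported in RNA space (T -> U).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: read-length screen applied on load, in nt
MIN_READ_LEN = 15
MAX_READ_LEN = 30

#: size bands used throughout: degradation products, Dicer products
#: (miRNA/siRNA-sized) and piRNAs; 25 nt belongs to no band.
DEGRADATION_BAND = (15, 17)
DICER_BAND = (18, 24)
PIRNA_BAND = (26, 30)


def to_rna(nt: str) -> str:
    """Map a DNA base to RNA space (T -> U); anything unknown -> N."""
    nt = nt.upper()
    if nt == "T":
        return "U"
    return nt if nt in "ACGUN" else "N"


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One ungapped genomic alignment of a small RNA.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    strand : str
        ``'+'`` or ``'-'``.
    start, end : int
        0-based half-open genomic interval; ``start < end``.
    first_nt : str
        The read's 5' nucleotide in RNA space (``A/C/G/U/N``).
    """

    chrom: str
    strand: str
    start: int
    end: int
    first_nt: str = "N"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end (end-1 on +, start on -)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Library:
    """A multiset of aligned reads plus the RPM denominator.

    ``total_alignments`` is the number of retained alignments and the only
    denominator used for RPM and percent calculations.
    """

    reads: list[AlignedRead]
    metadata: dict = field(default_factory=dict)
    load_log: dict = field(default_factory=dict)

    @property
    def total_alignments(self) -> int:
        return len(self.reads)

    @property
    def chroms(self) -> set[str]:
        return {r.chrom for r in self.reads}

    @property
    def name(self) -> str:
        return str(self.metadata.get("name", "library"))

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[AlignedRead]:
        return iter(self.reads)

    def read_multiset(self) -> Counter:
        """Multiset view for equality checks (round-trip tests)."""
        return Counter(self.reads)


def library_stats(library: Library) -> dict:
    """Desk-scale library summary: totals, per-length/strand/first-nt counts.

    Per-length counts always sum to ``total_alignments``.
    """
    by_length: Counter = Counter(r.length for r in library)
    by_strand: Counter = Counter(r.strand for r in library)
    by_first_nt: Counter = Counter(r.first_nt for r in library)
    by_chrom: Counter = Counter(r.chrom for r in library)
    return {
        "total_alignments": library.total_alignments,
        "by_length": dict(sorted(by_length.items())),
        "by_strand": {"+": by_strand.get("+", 0), "-": by_strand.get("-", 0)},
        "by_first_nt": dict(sorted(by_first_nt.items())),
        "by_chrom": dict(sorted(by_chrom.items())),
        "load_log": dict(library.load_log),
    }


def reads_sorted(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Deterministic canonical ordering of a read collection."""
    return sorted(reads, key=lambda r: (r.chrom, r.start, r.end, r.strand, r.first_nt))
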