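"""Reading and writing alignments, loci and genomes.

SAM/BAM goes through pysam; FASTA through Biopython.  Only primary,
mapped, ungapped alignments inside the length screen are retained; every
exclusion is counted by reason in the library's load log.  Internal
coordinates are 0-based half-open; SAM's 1-based closed convention is
converted at this boundary and BED is emitted natively.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedRead,
    Library,
    COMPLEMENT,
    MIN_READ_LEN,
    MAX_READ_LEN,
    to_rna,
    reads_sorted,
)
from .loci import Locus

_RNA_TO_DNA = {"A": "A", "C": "C", "G": "G", "U": "T", "N": "N"}


def _first_nt_from_seq(seq: str | None, strand: str) -> str:
    """5' nucleotide of the read given SAM SEQ (reference-forward)."""
    if not seq or seq == "*":
        return "N"
    base = seq[0] if strand == "+" else COMPLEMENT.get(seq[-1].upper(), "N")
    return to_rna(base)


def load_alignments(
    path,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    fmt: str | None = None,
    name: str | None = None,
) -> Library:
    """Load genome-aligned small-RNA reads from SAM/BAM or BED6.

    Applies the read-length screen (default 15-30 nt) and excludes
    unmapped, secondary/supplementary and gapped/spliced records.  The
    returned library's ``load_log`` reports input and per-reason exclusion
    counts; ``total_alignments`` is the retained count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() in (".bed", ".bed6") else "sam"
    if fmt == "bed":
        return _load_bed6(path, min_len, max_len, name)
    return _load_sam(path, min_len, max_len, name)


def _load_sam(path, min_len, max_len, name) -> Library:
    log = {
        "input_records": 0,
        "retained": 0,
        "excluded_unmapped": 0,
        "excluded_secondary": 0,
        "excluded_gapped": 0,
        "excluded_length": 0,
    }
    reads: list[AlignedRead] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        lengths = dict(zip(fh.references or (), fh.lengths or ()))
        for rec in fh.fetch(until_eof=True):
            log["input_records"] += 1
            if rec.is_unmapped:
                log["excluded_unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                log["excluded_secondary"] += 1
                continue
            cigar = rec.cigartuples or []
            # ungapped means alignment-match ops only (M/=/X)
            if not cigar or any(op not in (0, 7, 8) for op, _ in cigar):
                log["excluded_gapped"] += 1
                continue
            start = rec.reference_start
            end = rec.reference_end
            length = end - start
            if not (min_len <= length <= max_len):
                log["excluded_length"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            reads.append(
                AlignedRead(
                    chrom=rec.reference_name,
                    strand=strand,
                    start=start,
                    end=end,
                    first_nt=_first_nt_from_seq(rec.query_sequence, strand),
                )
            )
            log["retained"] += 1
    meta = {"name": name or path.stem, "source": str(path)}
    if lengths:
        meta["chrom_lengths"] = {str(k): int(v) for k, v in lengths.items()}
    return Library(reads=reads, metadata=meta, load_log=log)


def _load_bed6(path, min_len, max_len, name) -> Library:
    log = {"input_records": 0, "retained": 0, "excluded_length": 0}
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            log["input_records"] += 1
            chrom, start, end, rid, _score, strand = line.split("\t")[:6]
            start, end = int(start), int(end)
            if not (min_len <= end - start <= max_len):
                log["excluded_length"] += 1
                continue
            first_nt = rid.rsplit(":", 1)[-1] if ":" in rid else "N"
            reads.append(
                AlignedRead(
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    first_nt=first_nt if first_nt in "ACGUN" else "N",
                )
            )
            log["retained"] += 1
    return Library(reads=reads, metadata={"name": name or path.stem, "source": str(path)}, load_log=log)


def write_sam(library: Library, path, chrom_lengths: dict[str, int], genome=None) -> None:
    """Write a library as unsorted SAM.

    With ``genome`` (chrom -> base array/str) the full read sequence is
    emitted; otherwise only the 5' nucleotide is real and the rest is N,
    which still round-trips everything the internal model carries.
    """
    refs = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in refs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(library):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"r{i:07d}"
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = refs.index(r.chrom)
            seg.reference_start = r.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, r.length)]
            if genome is not None:
                chunk = genome[r.chrom][r.start : r.end]
                seg.query_sequence = "".join(chunk) if not isinstance(chunk, str) else chunk
            else:
                nt = _RNA_TO_DNA.get(r.first_nt, "N")
                if r.strand == "+":
                    seg.query_sequence = nt + "N" * (r.length - 1)
                else:
                    seg.query_sequence = "N" * (r.length - 1) + COMPLEMENT[nt]
            seg.query_qualities = None
            out.write(seg)


def write_bed6(library: Library, path) -> None:
    """Alignments as BED6; first_nt is encoded in the name column so the
    format carries the same information as the SAM output."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads_sorted(library.reads)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i:07d}:{r.first_nt}\t{r.length}\t{r.strand}\n")


def write_loci_bed(loci, path) -> None:
    """Loci as BED with id, read count, RPM, class and signature z extras."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tlocus_id\tread_count\tstrand\trpm\t"
            "class_label\tpingpong_z\tphasing_z\n"
        )
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.read_count}\t.\t{loc.rpm:.6f}\t{loc.class_label or '.'}\t"
                f"{_fmt_z(loc.pingpong_z)}\t{_fmt_z(loc.phasing_z)}\n"
            )


def _fmt_z(z) -> str:
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return "."
    return f"{z:.4f}"


def _parse_z(tok: str):
    return None if tok == "." else float(tok)


def read_loci_bed(path) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            loci.append(
                Locus(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    locus_id=f[3],
                    read_count=int(f[4]),
                    rpm=float(f[6]),
                    class_label=None if f[7] == "." else f[7],
                    pingpong_z=_parse_z(f[8]) if len(f) > 8 else None,
                    phasing_z=_parse_z(f[9]) if len(f) > 9 else None,
                )
            )
    return loci


def write_genome_fasta(genome, path) -> None:
    records = [
        SeqRecord(Seq("".join(seq) if not isinstance(seq, str) else seq), id=chrom, description="")
        for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_lengths(path) -> dict[str, int]:
    """Chromosome length table from FASTA, .fai, or two-column text."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            lengths[fields[0]] = int(fields[1])
    return lengths
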