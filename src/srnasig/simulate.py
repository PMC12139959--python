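"""Synthetic genomes and small-RNA libraries with planted biogenesis signatures.

The generator plants loci of five kinds, each defined by the read geometry
that diagnoses its biogenesis pathway:

``dicer_duplex``
    Opposite-strand read pairs with 2-nt 3' overhangs at BOTH duplex ends,
    the RNase III cleavage signature of siRNA duplexes (20-24 nt).
``pingpong_pirna``
    Opposite-strand piRNA pairs whose 5' ends overlap by exactly 10 nt,
    with 1U initiator / 10A responder composition (26-30 nt).
``phased_pirna``
    Same-strand head-to-tail trails of 1U reads (Zucchini phasing;
    next 5' start equals the previous read's end).
``mirna_like``
    Reads stacked at <=2 distinct 5' positions (mature/star), 21-23 nt.
``degradation``
    Uniformly placed short reads (<18 nt).

Every library comes with a machine-readable manifest recording, per planted
locus, the signature quantities a downstream scan must recover.  Those
expectations are computed here by a small all-pairs enumeration over the
locus's own reads, deliberately independent of the scan implementations, so
manifest cross-checks exercise two separate code paths.  With background
reads enabled, manifest expectations remain per-locus quantities and do not
account for accidental background/cross-locus pairs.

A fixed ``(config, seed)`` reproduces the genome, library and manifest
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import AlignedRead, Library, to_rna, COMPLEMENT

LOCUS_CLASSES = (
    "dicer_duplex",
    "pingpong_pirna",
    "phased_pirna",
    "mirna_like",
    "degradation",
)

#: class-default read-length ranges (nt, inclusive)
DEFAULT_LENGTH_RANGE = {
    "dicer_duplex": (20, 24),
    "pingpong_pirna": (26, 30),
    "phased_pirna": (26, 30),
    "mirna_like": (21, 23),
    "degradation": (15, 17),
}

#: class-default probability that a read's first nt is U
DEFAULT_U1_PROB = {
    "pingpong_pirna": 0.9,
    "phased_pirna": 0.9,
}
FALLBACK_U1_PROB = 0.25

_BASES = np.array(["A", "C", "G", "T"])
_NOT = {"T": ("A", "C", "G"), "A": ("C", "G", "T")}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(ValueError):
    """A planted locus does not fit inside its chromosome."""


@dataclass
class PlantedLocusSpec:
    """Specification of one planted small-RNA locus.

    ``n_reads`` counts emitted alignments; the paired classes
    (``dicer_duplex``, ``pingpong_pirna``) require an even count.
    ``span`` bounds the random 5'-offset window for classes that scatter
    reads (duplex, ping-pong, degradation); phased trails and miRNA stacks
    define their own extent.
    """

    class_label: str
    chrom: str
    anchor: int
    n_reads: int
    length_range: tuple[int, int] | None = None
    u1_prob: float | None = None
    a10_prob: float = 0.8
    span: int = 200

    def __post_init__(self) -> None:
        if self.class_label not in LOCUS_CLASSES:
            raise ConfigurationError(f"unknown locus class {self.class_label!r}")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        if self.length_range is None:
            self.length_range = DEFAULT_LENGTH_RANGE[self.class_label]
        if self.u1_prob is None:
            self.u1_prob = DEFAULT_U1_PROB.get(self.class_label, FALLBACK_U1_PROB)
        for p in (self.u1_prob, self.a10_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad length range {self.length_range}")
        if self.class_label in ("dicer_duplex", "pingpong_pirna") and self.n_reads % 2:
            raise ConfigurationError(f"{self.class_label} emits pairs; n_reads must be even")
        if self.anchor < 0 or self.span < 1:
            raise ConfigurationError("anchor must be >= 0 and span >= 1")


@dataclass
class SimConfig:
    """Simulation configuration: genome shape, planted loci, background."""

    n_chroms: int = 1
    chrom_length: int = 100_000
    seed: int = 0
    loci_specs: list[PlantedLocusSpec] = field(default_factory=list)
    background_reads: int = 0
    background_length_range: tuple[int, int] = (15, 17)
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_chroms < 1:
            raise ConfigurationError("n_chroms must be >= 1")
        if self.chrom_length < 1000:
            raise ConfigurationError("chrom_length must be >= 1000")
        if self.background_reads < 0:
            raise ConfigurationError("background_reads must be >= 0")
        lo, hi = self.background_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad background length range {(lo, hi)}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background_length_range"] = list(self.background_length_range)
        for spec in d["loci_specs"]:
            spec["length_range"] = list(spec["length_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        specs = [
            PlantedLocusSpec(
                **{
                    **s,
                    "length_range": tuple(s["length_range"]) if s.get("length_range") else None,
                }
            )
            for s in d.pop("loci_specs", [])
        ]
        if "background_length_range" in d:
            d["background_length_range"] = tuple(d["background_length_range"])
        return cls(loci_specs=specs, **d)


@dataclass
class PlantedLocusTruth:
    """Ground truth for one planted locus: placement and expected signatures."""

    class_label: str
    chrom: str
    start: int
    end: int
    n_reads: int
    expected: dict


@dataclass
class SimManifest:
    """Ground truth of one simulated library, reproducible from (config, seed)."""

    seed: int
    loci: list[PlantedLocusTruth]
    n_background: int
    total_alignments: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_background": self.n_background,
            "total_alignments": self.total_alignments,
            "loci": [asdict(l) for l in self.loci],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            n_background=d["n_background"],
            total_alignments=d["total_alignments"],
            loci=[PlantedLocusTruth(**l) for l in d["loci"]],
        )


def generate_genome(config: SimConfig) -> dict[str, np.ndarray]:
    """Random uniform {A,C,G,T} genome; deterministic under ``config.seed``.

    Returns per-chromosome mutable base arrays (dtype ``<U1``); use
    :func:`genome_lengths` / :func:`write_genome_fasta` for derived views.
    """
    rng = np.random.default_rng(config.seed)
    return {
        name: _BASES[rng.integers(0, 4, size=config.chrom_length)]
        for name in config.chrom_names
    }


def genome_lengths(genome: dict[str, np.ndarray]) -> dict[str, int]:
    return {chrom: int(len(seq)) for chrom, seq in genome.items()}


def _set_first_nt(genome_seq, pos, strand, want_u, rng) -> None:
    """Force the genomic base so the read starting at ``pos`` begins with
    U (``want_u``) or an exactly non-U base drawn uniformly."""
    base_for_u = "T" if strand == "+" else "A"
    if want_u:
        genome_seq[pos] = base_for_u
    else:
        genome_seq[pos] = rng.choice(_NOT[base_for_u])


def _read_from_genome(genome_seq, chrom, strand, start, end) -> AlignedRead:
    if strand == "+":
        first = to_rna(str(genome_seq[start]))
    else:
        first = to_rna(COMPLEMENT[str(genome_seq[end - 1])])
    return AlignedRead(chrom=chrom, strand=strand, start=start, end=end, first_nt=first)


def plant_locus(
    genome: dict[str, np.ndarray], spec: PlantedLocusSpec, rng: np.random.Generator
) -> list[AlignedRead]:
    """Emit the reads of one planted locus, mutating the genome so that
    planted 1U/10A biases are consistent with the genomic sequence.

    Raises :class:`PlacementError` when any read would extend outside the
    chromosome.
    """
    if spec.chrom not in genome:
        raise PlacementError(f"unknown chromosome {spec.chrom!r}")
    seq = genome[spec.chrom]
    chrom_len = len(seq)
    lo, hi = spec.length_range
    a = spec.anchor
    reads: list[AlignedRead] = []

    def check(start: int, end: int) -> None:
        if start < 0 or end > chrom_len:
            raise PlacementError(
                f"{spec.class_label} locus at {spec.chrom}:{a} places a read "
                f"[{start},{end}) outside [0,{chrom_len})"
            )

    if spec.class_label == "dicer_duplex":
        for _ in range(spec.n_reads // 2):
            L = int(rng.integers(lo, hi + 1))
            off = int(rng.integers(0, spec.span))
            ps, pe = a + off, a + off + L
            ms, me = ps - 2, pe - 2  # both-end 2-nt 3' overhangs
            check(ms, pe)
            _set_first_nt(seq, ps, "+", rng.random() < spec.u1_prob, rng)
            _set_first_nt(seq, me - 1, "-", rng.random() < spec.u1_prob, rng)
            reads.append(_read_from_genome(seq, spec.chrom, "+", ps, pe))
            reads.append(_read_from_genome(seq, spec.chrom, "-", ms, me))
    elif spec.class_label == "pingpong_pirna":
        for _ in range(spec.n_reads // 2):
            l_resp = int(rng.integers(lo, hi + 1))
            l_init = int(rng.integers(lo, hi + 1))
            off = int(rng.integers(0, spec.span))
            p5 = a + off
            ps, pe = p5, p5 + l_resp  # plus-strand responder
            ms, me = p5 + 10 - l_init, p5 + 10  # minus-strand initiator; 5' at p5+9
            check(min(ps, ms), max(pe, me))
            # initiator 1U at genome[p5+9]='A' is, by duplex geometry, the
            # responder's position-10 A — a10_prob drives both at once
            _set_first_nt(seq, p5 + 9, "-", rng.random() < spec.a10_prob, rng)
            _set_first_nt(seq, p5, "+", rng.random() < spec.u1_prob, rng)
            reads.append(_read_from_genome(seq, spec.chrom, "+", ps, pe))
            reads.append(_read_from_genome(seq, spec.chrom, "-", ms, me))
    elif spec.class_label == "phased_pirna":
        pos = a
        for _ in range(spec.n_reads):
            L = int(rng.integers(lo, hi + 1))
            check(pos, pos + L)
            _set_first_nt(seq, pos, "+", rng.random() < spec.u1_prob, rng)
            reads.append(_read_from_genome(seq, spec.chrom, "+", pos, pos + L))
            pos += L  # head-to-tail: next 5' start = previous end
    elif spec.class_label == "mirna_like":
        positions = [a, a + 35]  # mature + star arm, <=2 distinct 5' stacks
        for pos in positions:
            _set_first_nt(seq, pos, "+", rng.random() < spec.u1_prob, rng)
        n_major = max(1, int(round(spec.n_reads * 0.8)))
        for i in range(spec.n_reads):
            L = int(rng.integers(lo, hi + 1))
            pos = positions[0] if i < n_major else positions[1]
            check(pos, pos + L)
            reads.append(_read_from_genome(seq, spec.chrom, "+", pos, pos + L))
    elif spec.class_label == "degradation":
        for _ in range(spec.n_reads):
            L = int(rng.integers(lo, hi + 1))
            off = int(rng.integers(0, spec.span))
            strand = "+" if rng.random() < 0.5 else "-"
            check(a + off, a + off + L)
            reads.append(_read_from_genome(seq, spec.chrom, strand, a + off, a + off + L))
    return reads


# ---------------------------------------------------------------------------
# Inline expectation oracles (independent of srnasig.signatures on purpose)


def _expected_dicer(reads, min_len=20, max_len=24, overhang=2):
    plus = [(i, r) for i, r in enumerate(reads) if r.strand == "+" and min_len <= r.length <= max_len]
    minus = [(i, r) for i, r in enumerate(reads) if r.strand == "-" and min_len <= r.length <= max_len]
    n_pairs = 0
    members: set[int] = set()
    for i, p in plus:
        for j, m in minus:
            if p.chrom == m.chrom and p.start - m.start == overhang and p.end - m.end == overhang:
                n_pairs += 1
                members.add(i)
                members.add(j)
    return n_pairs, len(members)


def _expected_pingpong10(reads):
    n = 0
    for p in reads:
        if p.strand != "+":
            continue
        for m in reads:
            if m.strand == "-" and m.chrom == p.chrom and m.five_prime - p.five_prime + 1 == 10:
                n += 1
    return n


def _expected_phased_d1(reads):
    n = 0
    for k, w in enumerate(reads):
        if w.first_nt != "U":
            continue
        best = None
        for j, u in enumerate(reads):
            if j == k or u.strand != w.strand or u.chrom != w.chrom:
                continue
            if w.strand == "+":
                if u.end <= w.start and (best is None or u.end > best):
                    best = u.end
            else:
                if u.start >= w.end and (best is None or u.start < best):
                    best = u.start
        if best is None:
            continue
        d = (w.start - best + 1) if w.strand == "+" else (best - w.end + 1)
        if d == 1:
            n += 1
    return n


def _locus_truth(spec: PlantedLocusSpec, reads: list[AlignedRead]) -> PlantedLocusTruth:
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    n_pairs, n_members = _expected_dicer(reads)
    expected = {
        "dicer_pairs": n_pairs,
        "dicer_member_alignments": n_members,
        "pingpong_pairs_at_10": _expected_pingpong10(reads),
        "phased_adjacent_d1": _expected_phased_d1(reads),
        "n_first_u": sum(1 for r in reads if r.first_nt == "U"),
    }
    return PlantedLocusTruth(
        class_label=spec.class_label,
        chrom=spec.chrom,
        start=start,
        end=end,
        n_reads=len(reads),
        expected=expected,
    )


def simulate_library(config: SimConfig) -> tuple[Library, SimManifest, dict[str, np.ndarray]]:
    """Generate (library, manifest, genome) for a configuration.

    Reads are emitted locus by locus in spec order, then background reads
    are placed uniformly (strand Bernoulli(0.5)).  Planted loci must not
    overlap unless ``config.allow_overlap`` is set.
    """
    genome = generate_genome(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    per_locus: list[tuple[PlantedLocusSpec, list[AlignedRead]]] = []
    for spec in config.loci_specs:
        per_locus.append((spec, plant_locus(genome, spec, rng)))
    # overlapping planted writes can retarget a base another read starts on;
    # re-derive every first_nt from the final genome so reads, manifest and
    # any sequence output agree
    per_locus = [
        (spec, [_read_from_genome(genome[r.chrom], r.chrom, r.strand, r.start, r.end)
                for r in locus_reads])
        for spec, locus_reads in per_locus
    ]
    reads: list[AlignedRead] = []
    truths: list[PlantedLocusTruth] = []
    for spec, locus_reads in per_locus:
        truths.append(_locus_truth(spec, locus_reads))
        reads.extend(locus_reads)
    if not config.allow_overlap:
        ivals = sorted((t.chrom, t.start, t.end) for t in truths)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivals, ivals[1:]):
            if c1 == c2 and s2 < e1:
                raise ConfigurationError(
                    f"planted loci overlap on {c1} ([{s1},{e1}) vs [{s2},{e2})); "
                    "set allow_overlap=True to permit"
                )
    lo, hi = config.background_length_range
    names = config.chrom_names
    nb = config.background_reads
    if nb:
        chrom_idx = rng.integers(0, config.n_chroms, size=nb)
        lens = rng.integers(lo, hi + 1, size=nb)
        starts = (rng.random(size=nb) * (config.chrom_length - lens + 1)).astype(np.int64)
        minus = rng.random(size=nb) < 0.5
        for ci, L, s, mi in zip(chrom_idx, lens, starts, minus):
            chrom = names[ci]
            s = int(s)
            L = int(L)
            if mi:
                first = to_rna(COMPLEMENT[str(genome[chrom][s + L - 1])])
                reads.append(AlignedRead(chrom, "-", s, s + L, first))
            else:
                reads.append(AlignedRead(chrom, "+", s, s + L, to_rna(str(genome[chrom][s]))))
    library = Library(reads=reads, metadata={"name": f"sim_seed{config.seed}", "seed": config.seed})
    manifest = SimManifest(
        seed=config.seed,
        loci=truths,
        n_background=config.background_reads,
        total_alignments=len(reads),
    )
    return library, manifest, genome
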