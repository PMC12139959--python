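"""Canned simulation scenarios: the standard conditions used for
calibration, contrast and recovery checks.

These are thin builders over :mod:`srnasig.simulate` that fix the study
designs referenced throughout the tests and the acceptance script:

* a background-only null library (uniform placement) for z-score
  calibration;
* a library with a chosen fraction of its alignments planted as Dicer
  duplex pairs, against an equal-size background-only twin, for the
  five-fold siRNA contrast;
* planted Ping-Pong / phased loci at 10x background for signal detection;
* a mixed-class library of many planted loci for end-to-end
  classification accuracy.

Background length ranges: the calibration null uses the full screened
range (15-30 nt) so every histogram bin is populated; class defaults
elsewhere follow the generator.
"""

from __future__ import annotations

import numpy as np

from .model import Library
from .simulate import PlantedLocusSpec, SimConfig, SimManifest, simulate_library

#: planted-class -> expected classification label
EXPECTED_LABEL = {
    "dicer_duplex": "dicer-product-like",
    "pingpong_pirna": "piRNA-like",
    "phased_pirna": "piRNA-like",
    "mirna_like": "dicer-product-like",
    "degradation": "degradation-like",
}


#: the fixed null-calibration condition: desk-scale density on 1 Mb,
#: ~100 overlap counts and ~50 phasing counts per histogram bin
NULL_READS = 20_000
NULL_CHROM_LENGTH = 1_000_000


def null_library(seed: int) -> Library:
    """The canonical background-only calibration library."""
    return background_only(seed, n_reads=NULL_READS, chrom_length=NULL_CHROM_LENGTH)


def background_only(seed: int, n_reads: int = 4000, chrom_length: int = 200_000,
                    length_range: tuple[int, int] = (15, 30)) -> Library:
    """Uniformly placed reads, strand Bernoulli(0.5): the null library."""
    cfg = SimConfig(
        n_chroms=1,
        chrom_length=chrom_length,
        seed=seed,
        background_reads=n_reads,
        background_length_range=length_range,
    )
    library, _, _ = simulate_library(cfg)
    return library


def dicer_contrast_pair(seed: int, n_reads: int = 4000, duplex_fraction: float = 0.05,
                        chrom_length: int = 200_000) -> tuple[Library, Library]:
    """(planted, null) libraries of equal size for the five-fold contrast.

    The planted library carries ``duplex_fraction`` of its alignments as
    Dicer duplex pairs; both libraries use a 15-30 nt background so the
    null percent is a genuine (nonzero-capable) baseline.
    """
    n_duplex = int(round(n_reads * duplex_fraction))
    n_duplex -= n_duplex % 2
    cfg = SimConfig(
        n_chroms=1,
        chrom_length=chrom_length,
        seed=seed,
        loci_specs=[
            PlantedLocusSpec("dicer_duplex", "chr1", 1000, n_duplex, span=400)
        ],
        background_reads=n_reads - n_duplex,
        background_length_range=(15, 30),
    )
    planted, _, _ = simulate_library(cfg)
    null = background_only(seed + 1_000_000, n_reads=n_reads, chrom_length=chrom_length)
    return planted, null


def planted_signal_library(seed: int, kind: str, n_signal: int = 400,
                           background_reads: int = 0) -> tuple[Library, SimManifest]:
    """One planted Ping-Pong or phased locus, optional uniform background."""
    assert kind in ("pingpong_pirna", "phased_pirna")
    cfg = SimConfig(
        n_chroms=1,
        chrom_length=200_000,
        seed=seed,
        loci_specs=[PlantedLocusSpec(kind, "chr1", 50_000, n_signal, span=300)],
        background_reads=background_reads,
        background_length_range=(26, 30),
    )
    library, manifest, _ = simulate_library(cfg)
    return library, manifest


def mixed_class_library(seed: int, n_loci: int = 100, reads_per_locus: int = 60,
                        background_reads: int = 0,
                        classes: tuple[str, ...] = (
                            "dicer_duplex",
                            "pingpong_pirna",
                            "phased_pirna",
                            "mirna_like",
                            "degradation",
                        )) -> tuple[Library, SimManifest]:
    """Many planted loci cycling through ``classes`` on a 4-kb locus grid.

    The spacing keeps even the longest phased trails (<3 kb) more than the
    500-bp merge distance away from their neighbours, so planted loci stay
    separate at the default operating point.  Spread over as many
    chromosomes as needed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    per_chrom = 25
    n_chroms = (n_loci + per_chrom - 1) // per_chrom
    specs = []
    for i in range(n_loci):
        cls = classes[i % len(classes)]
        chrom = f"chr{i // per_chrom + 1}"
        anchor = 1000 + (i % per_chrom) * 4000
        n_reads = reads_per_locus + int(rng.integers(0, 20)) * 2
        specs.append(PlantedLocusSpec(cls, chrom, anchor, n_reads, span=150))
    cfg = SimConfig(
        n_chroms=n_chroms,
        chrom_length=per_chrom * 4000 + 2000,
        seed=seed,
        loci_specs=specs,
        background_reads=background_reads,
    )
    library, manifest, _ = simulate_library(cfg)
    return library, manifest


def random_library(seed: int, n_reads: int, chrom_length: int = 10_000,
                   n_chroms: int = 1, length_range: tuple[int, int] = (15, 30)) -> Library:
    """Small uniform library for oracle-equivalence scans."""
    cfg = SimConfig(
        n_chroms=n_chroms,
        chrom_length=max(chrom_length, 1000),
        seed=seed,
        background_reads=n_reads,
        background_length_range=length_range,
    )
    library, _, _ = simulate_library(cfg)
    return library


def match_planted_labels(manifest: SimManifest, loci, classes) -> tuple[int, int]:
    """Score recovered labels against planted truth.

    For each planted locus, find a recovered locus overlapping it and
    compare the recovered label with the planted class's expected label.
    Returns (n_correct, n_planted); an unrecovered planted locus counts
    as wrong.
    """
    labels = dict(zip(classes.index, classes["label"]))
    n_correct = 0
    for truth in manifest.loci:
        hit = None
        for loc in loci:
            if loc.chrom == truth.chrom and loc.start < truth.end and truth.start < loc.end:
                hit = loc
                break
        if hit is not None and labels.get(hit.locus_id) == EXPECTED_LABEL[truth.class_label]:
            n_correct += 1
    return n_correct, len(manifest.loci)
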