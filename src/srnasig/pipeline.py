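"""End-to-end pipeline: load -> signatures -> loci -> profile -> quant.

Every run writes its resolved configuration next to the outputs as a
provenance record, and all artifacts are plain text with no timestamps,
so a rerun with the same configuration and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as sio
from .loci import annotate_loci, threshold_sweep, genome_fraction, MERGE_GRID, RPM_GRID
from .model import Library, library_stats
from .profiles import (
    classify_loci,
    cluster_order,
    locus_size_matrix,
    per_locus_signatures,
    z_normalize_rows,
)
from .quant import count_matrix, export_counts
from .signatures import dicer_pair_fraction, overlap_histogram, phasing_histogram, size_distribution

logger = logging.getLogger("srnasig")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the operating point used throughout: 15-30 nt screen,
    20-24 nt Dicer window with 2-nt overhangs, merge within 500 bp, keep
    loci >= 1000 RPM, Ping-Pong focal overlap 10, phasing focal distance 1.
    """

    input_path: str = ""
    genome_lengths_path: str | None = None
    out_dir: str = "srnasig_out"
    min_len: int = 15
    max_len: int = 30
    pair_min_len: int = 20
    pair_max_len: int = 24
    overhang: int = 2
    max_overlap: int = 30
    max_phasing_dist: int = 9
    merge_distance: int = 500
    min_rpm: float = 1000.0
    pirna_frac: float = 0.5
    dicer_frac: float = 0.5
    z_min: float = 2.0
    run_sweep: bool = True
    pirna_band_counts: bool = False
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig, library: Library | None = None) -> dict:
    """Execute the full flow and write the artifact set.

    ``library`` may be passed directly (e.g. a freshly simulated one);
    otherwise ``config.input_path`` is loaded.  Returns a dict of artifact
    paths and headline numbers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    if library is None:
        if not config.input_path or not Path(config.input_path).exists():
            raise PipelineError(f"stage 'load' failed: missing input {config.input_path!r}")
        library = _stage("load")(
            sio.load_alignments, config.input_path, config.min_len, config.max_len
        )
    logger.info("load: %d alignments retained", library.total_alignments)

    if config.genome_lengths_path:
        glens = _stage("load")(sio.read_genome_lengths, config.genome_lengths_path)
    elif "chrom_lengths" in library.metadata:
        glens = library.metadata["chrom_lengths"]
    else:
        glens = {c: max(r.end for r in library if r.chrom == c) for c in sorted(library.chroms)}

    stats = {"library": library_stats(library)}
    sig = _stage("signatures")
    stats["dicer_pair_percent"] = sig(
        dicer_pair_fraction, library, config.pair_min_len, config.pair_max_len, config.overhang
    )
    ov = sig(overlap_histogram, library, config.max_overlap)
    ph = sig(phasing_histogram, library, config.max_phasing_dist)
    sizes = sig(size_distribution, library)
    stats["pingpong"] = {"counts": ov.counts, "z": ov.z}
    stats["phasing"] = {"counts": ph.counts, "z": ph.z}
    stats["size_bands"] = sizes.band_fractions()
    logger.info(
        "signatures: dicer %.3f%%, ping-pong z %.2f, phasing z %.2f",
        stats["dicer_pair_percent"], ov.z, ph.z,
    )

    loci_stage = _stage("loci")
    loci = loci_stage(annotate_loci, library, config.merge_distance, config.min_rpm)
    stats["n_loci"] = len(loci)
    stats["genome_fraction_pct"] = genome_fraction(loci, glens) if glens else 0.0
    sweep_path = None
    if config.run_sweep:
        sweep = loci_stage(threshold_sweep, library, glens, MERGE_GRID, RPM_GRID)
        sweep_path = out / "sweep.tsv"
        sweep.to_csv(sweep_path, sep="\t", index=False)
    logger.info("loci: %d at merge %d / >=%g RPM", len(loci), config.merge_distance, config.min_rpm)

    prof = _stage("profile")
    size_mat = prof(locus_size_matrix, loci, library)
    zs = prof(per_locus_signatures, loci, library)
    classes = prof(
        classify_loci, size_mat, zs,
        pirna_frac=config.pirna_frac, dicer_frac=config.dicer_frac, z_min=config.z_min,
    )
    zmat = z_normalize_rows(size_mat)
    order = cluster_order(zmat) if len(loci) else []
    zmat = zmat.iloc[order]
    for locus, pp, phz, label in zip(
        loci, classes["pingpong_z"], classes["phasing_z"], classes["label"]
    ):
        locus.pingpong_z, locus.phasing_z, locus.class_label = float(pp), float(phz), str(label)
    stats["class_counts"] = classes["label"].value_counts().to_dict()

    qm = _stage("quant")(
        count_matrix, loci, [library], "pirna" if config.pirna_band_counts else None
    )

    paths = {
        "stats": out / "stats.json",
        "loci_bed": out / "loci.bed",
        "size_matrix": out / "size_matrix.tsv",
        "classes": out / "classes.tsv",
        "counts": out / "counts.tsv",
        "config": out / "resolved_config.yaml",
    }
    if sweep_path:
        paths["sweep"] = sweep_path
    with open(paths["stats"], "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    sio.write_loci_bed(loci, paths["loci_bed"])
    zmat.to_csv(paths["size_matrix"], sep="\t", index_label="locus_id")
    classes.to_csv(paths["classes"], sep="\t", index_label="locus_id")
    export_counts(qm, paths["counts"])
    return {"paths": {k: str(v) for k, v in paths.items()}, "stats": stats, "loci": loci}


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(name)s %(levelname)s %(message)s",
    )
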