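# srnasig

Small-RNA biogenesis signatures, locus annotation and read-size profiling
for genome-aligned sRNA-seq libraries — with a simulator that plants every
signature alongside a machine-readable truth manifest, so the whole
pipeline is testable without touching real sequencing data.

## The problem

Animal small-RNA populations are made by three pathways that leave
distinct geometric fingerprints in read alignments:

* **siRNAs** are diced from long dsRNA by an RNase III enzyme that leaves
  **2-nt 3′ overhangs** on both ends of each ~20–24 nt duplex. In
  alignments this shows up as opposite-strand read pairs *p* (plus) and
  *m* (minus) with `p.start − m.start = 2` **and** `p.end − m.end = 2`.
  The *Dicer-pair percent* — 100 × (alignments belonging to ≥1 such
  pair) / (total alignments) — indexes endogenous siRNA production;
  species lacking the pathway score several-fold lower than species that
  have it.
* **piRNAs** (~26–30 nt) arise without Dicer, via the **Ping-Pong**
  amplification loop (opposite-strand pairs whose 5′ ends overlap by
  exactly 10 nt, with 1U initiator / 10A responder bias) and **Zucchini
  phasing** (same-strand head-to-tail trails of 1U reads, so the distance
  from an upstream read's 3′ end to the next 1U read's 5′ end
  concentrates at d = 1). Each is summarised by a focal-bin z-score
  `z = (c_focal − mean(c_bg)) / sd(c_bg)` over the histogram's non-focal
  bins (population sd; ±10 cap when the background is flat).
* **miRNAs** (~21–23 nt) stack at one or two discrete 5′ positions.

On top of the signatures, the package annotates **sRNA-expressing loci**
(maximal intervals of read coverage, merged when gaps are within a merge
distance, then filtered by RPM = reads per million mapped alignments),
sweeps the merge-distance × depth grid to pick an operating point,
classifies each locus from its read-size profile (degradation < 18 nt,
Dicer products 18–24 nt, piRNA 26–30 nt) plus its signature z-scores, and
builds per-locus count matrices across libraries with RPM/log2 views and
PCA coordinates for export to differential-expression tools.

## Worked example

```python
from srnasig import (SimConfig, PlantedLocusSpec, simulate_library,
                     dicer_pair_fraction, overlap_histogram, phasing_histogram,
                     annotate_loci, locus_size_matrix, per_locus_signatures,
                     classify_loci)

cfg = SimConfig(
    n_chroms=1, chrom_length=100_000, seed=5,
    loci_specs=[
        PlantedLocusSpec("dicer_duplex",   "chr1",  1_000, 100),
        PlantedLocusSpec("pingpong_pirna", "chr1", 10_000, 400),
        PlantedLocusSpec("phased_pirna",   "chr1", 30_000,  50),
    ],
    background_reads=500,
)
library, manifest, genome = simulate_library(cfg)

print(round(dicer_pair_fraction(library), 2))   # 9.52
print(round(overlap_histogram(library).z, 2))   # 15.46
print(round(phasing_histogram(library).z, 2))   # 3.38

loci = annotate_loci(library, merge_distance=500, min_rpm=1000.0)
classes = classify_loci(locus_size_matrix(loci, library),
                        per_locus_signatures(loci, library))
print(classes["label"].value_counts().to_dict())
```

prints

```
9.52
15.46
3.38
{'degradation-like': 31, 'piRNA-like': 2, 'dicer-product-like': 1}
```

The Dicer-pair percent is 9.52% because the 100 planted duplex alignments
(plus a handful of accidental pairs) sit in a 1,050-alignment library; the
Ping-Pong z-score of 15.5 reflects the planted overlap-10 pairs against
the other 29 overlap bins, and the phasing z of 3.4 the head-to-tail 1U
trail (a 50-read trail against a 1,000-read library is a modest but
detectable signal). The locus table recovers all three planted loci with
the right labels; the 31 degradation-like calls are the scattered 15–17 nt
background reads, which in a library this small clear the ≥1000 RPM bar.

The same flow is available from the shell:

```bash
srnasig simulate --config sim.yaml -o simdir/
srnasig signatures simdir/reads.sam -o signatures.json
srnasig loci simdir/reads.sam --merge 500 --min-rpm 1000 -o loci.bed
srnasig sweep simdir/reads.sam --genome simdir/genome.fa -o sweep.tsv
srnasig profile simdir/reads.sam loci.bed -o classes.tsv --heatmap matrix.tsv
srnasig quant loci.bed simdir/reads.sam -o counts.tsv --pirna-band
srnasig run -c pipeline.yaml
```

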