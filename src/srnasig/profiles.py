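"""Per-locus read-size profiles and locus classification.

Each locus gets a row of read counts over lengths 15-30 nt; rows are
Z-normalized (population sd; constant rows map to zeros) and ordered by
hierarchical clustering for heatmap display.  Classification combines the
size bands with the per-locus Ping-Pong/phasing z-scores:

* piRNA-like — piRNA band (26-30 nt) fraction >= ``pirna_frac`` AND at
  least one of the piRNA signature z-scores >= ``z_min``;
* dicer-product-like — Dicer band (18-24 nt) fraction >= ``dicer_frac``;
* degradation-like — <18 nt band fraction >= 0.5;
* ambiguous otherwise, with precedence piRNA > dicer-product >
  degradation.

Length 25 nt belongs to no band and counts only toward totals.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list

from .model import Library, DEGRADATION_BAND, DICER_BAND, PIRNA_BAND, MIN_READ_LEN, MAX_READ_LEN
from .signatures import overlap_histogram, phasing_histogram

LENGTH_COLUMNS = list(range(MIN_READ_LEN, MAX_READ_LEN + 1))

#: minimum reads for a per-locus signature z-score to be defined
MIN_READS_FOR_Z = 10

LABELS = ("piRNA-like", "dicer-product-like", "degradation-like", "ambiguous")


def _locus_reads(loci, library: Library) -> list[list]:
    """Reads per locus by 5'-end containment; loci must be disjoint."""
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start))
    for a, b in zip(order, order[1:]):
        la, lb = loci[a], loci[b]
        if la.chrom == lb.chrom and lb.start < la.end:
            raise ValueError(f"overlapping loci {la.locus_id or a} and {lb.locus_id or b}")
    by_chrom = defaultdict(list)
    for i in order:
        by_chrom[loci[i].chrom].append(i)
    out: list[list] = [[] for _ in loci]
    for r in library:
        for i in by_chrom.get(r.chrom, ()):
            loc = loci[i]
            if loc.start <= r.five_prime < loc.end:
                out[i].append(r)
                break
            if loc.start > r.five_prime:
                break
    return out


def _locus_ids(loci) -> list[str]:
    return [loc.locus_id or f"locus_{i + 1:05d}" for i, loc in enumerate(loci)]


def locus_size_matrix(loci, library: Library) -> pd.DataFrame:
    """Loci x read-length count matrix; cell (l, s) counts reads of length
    s whose 5' end lies in locus l, so row sums equal locus read counts."""
    ids = _locus_ids(loci)
    mat = np.zeros((len(loci), len(LENGTH_COLUMNS)), dtype=np.int64)
    for i, reads in enumerate(_locus_reads(loci, library)):
        for r in reads:
            if MIN_READ_LEN <= r.length <= MAX_READ_LEN:
                mat[i, r.length - MIN_READ_LEN] += 1
    return pd.DataFrame(mat, index=ids, columns=LENGTH_COLUMNS)


def z_normalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (x - mean) / population sd; constant rows become zeros."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    out = np.zeros_like(values)
    nz = (sd > 0).ravel()
    out[nz] = (values[nz] - mean[nz]) / sd[nz]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cluster_order(matrix: pd.DataFrame, metric: str = "euclidean", method: str = "average") -> list[int]:
    """Row permutation from agglomerative-clustering leaf order.

    Deterministic for a fixed input (scipy's linkage breaks ties by the
    lower index).  Fewer than 2 rows returns the identity permutation.
    """
    n = matrix.shape[0]
    if n < 2:
        return list(range(n))
    Z = linkage(matrix.to_numpy(dtype=float), method=method, metric=metric)
    return [int(i) for i in leaves_list(Z)]


def per_locus_signatures(loci, library: Library, min_reads: int = MIN_READS_FOR_Z) -> pd.DataFrame:
    """Ping-Pong and phasing z-scores per locus, restricted to each locus's
    own reads; loci with fewer than ``min_reads`` reads get NaN."""
    rows = []
    for loc, reads in zip(loci, _locus_reads(loci, library)):
        if len(reads) < min_reads:
            pp = ph = math.nan
        else:
            pp = overlap_histogram(reads).z
            ph = phasing_histogram(reads).z
        rows.append({"n_reads": len(reads), "pingpong_z": pp, "phasing_z": ph})
    return pd.DataFrame(rows, index=_locus_ids(loci))


def classify_loci(
    size_matrix: pd.DataFrame,
    signature_zs: pd.DataFrame,
    pirna_frac: float = 0.5,
    dicer_frac: float = 0.5,
    degradation_frac: float = 0.5,
    z_min: float = 2.0,
) -> pd.DataFrame:
    """Label each locus from its size-band fractions and signature z-scores.

    Returns a frame indexed like ``size_matrix`` with the three band
    fractions, both z-scores and the label.
    """
    for frac in (pirna_frac, dicer_frac, degradation_frac):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"band-fraction threshold {frac} outside [0, 1]")
    if z_min < 0:
        raise ValueError("z_min must be >= 0")
    cols = np.asarray(size_matrix.columns, dtype=int)
    values = size_matrix.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)

    def band(lo, hi):
        mask = (cols >= lo) & (cols <= hi)
        return values[:, mask].sum(axis=1) / safe

    deg = band(*DEGRADATION_BAND)
    dcr = band(*DICER_BAND)
    pir = band(*PIRNA_BAND)
    zs = signature_zs.reindex(size_matrix.index)
    pp = zs["pingpong_z"].to_numpy(dtype=float)
    ph = zs["phasing_z"].to_numpy(dtype=float)
    z_ok = (np.nan_to_num(pp, nan=-np.inf) >= z_min) | (np.nan_to_num(ph, nan=-np.inf) >= z_min)
    labels = np.full(len(size_matrix), "ambiguous", dtype=object)
    labels[deg >= degradation_frac] = "degradation-like"
    labels[dcr >= dicer_frac] = "dicer-product-like"
    labels[(pir >= pirna_frac) & z_ok] = "piRNA-like"
    return pd.DataFrame(
        {
            "degradation_frac": deg,
            "dicer_frac": dcr,
            "pirna_frac": pir,
            "pingpong_z": pp,
            "phasing_z": ph,
            "label": labels,
        },
        index=size_matrix.index,
    )
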