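"""Per-locus count matrices across libraries, normalization and ordination.

Counts feed external differential-expression tools; this module only
exports integer counts, RPM / log2(RPM + pseudocount) views, naive fold
changes (explicitly not a DE test) and PCA coordinates of the libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Library, PIRNA_BAND
from .profiles import _locus_reads, _locus_ids


@dataclass
class CountMatrix:
    """Loci x libraries integer counts plus per-library RPM denominators."""

    counts: pd.DataFrame
    totals: pd.Series  # per-library total_alignments (RPM denominator)
    size_band: str | None = None

    def __post_init__(self) -> None:
        self.totals = self.totals.reindex(self.counts.columns)

    def rpm(self) -> pd.DataFrame:
        if (self.totals <= 0).any():
            raise ValueError("zero column total: RPM undefined")
        return self.counts / self.totals * 1e6

    def log2_rpm(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.rpm() + pseudocount)


def count_matrix(loci, libraries: list[Library], size_band: str | None = None) -> CountMatrix:
    """Count reads with 5' end in each locus, per library.

    ``size_band='pirna'`` restricts to 26-30 nt reads (piRNA-sized
    expression at piRNA loci); ``None`` counts everything.  A library whose
    chromosomes share nothing with the loci is treated as a genome
    mismatch and rejected.
    """
    if size_band not in (None, "pirna"):
        raise ValueError(f"unknown size band {size_band!r}")
    locus_chroms = {l.chrom for l in loci}
    names, columns, totals = [], [], {}
    for i, lib in enumerate(libraries):
        name = lib.metadata.get("name") or f"lib{i + 1}"
        if loci and len(lib) and not (locus_chroms & lib.chroms):
            raise ValueError(f"library {name!r} shares no chromosomes with the loci")
        col = []
        for reads in _locus_reads(loci, lib):
            if size_band == "pirna":
                lo, hi = PIRNA_BAND
                reads = [r for r in reads if lo <= r.length <= hi]
            col.append(len(reads))
        names.append(str(name))
        columns.append(col)
        totals[str(name)] = lib.total_alignments
    df = pd.DataFrame(
        np.array(columns, dtype=np.int64).T if columns else np.zeros((len(loci), 0), dtype=np.int64),
        index=_locus_ids(loci),
        columns=names,
    )
    return CountMatrix(counts=df, totals=pd.Series(totals, dtype=np.int64), size_band=size_band)


def normalize(matrix: CountMatrix, method: str = "rpm", pseudocount: float = 1.0) -> pd.DataFrame:
    """RPM or log2(RPM + pseudocount) view of a count matrix."""
    if method == "rpm":
        return matrix.rpm()
    if method == "log2_rpm":
        return matrix.log2_rpm(pseudocount)
    raise ValueError(f"unknown normalization {method!r}")


def pca_coords(log_matrix: pd.DataFrame, n_components: int = 2):
    """PCA of the libraries (columns) on their per-locus profiles.

    Columns are the samples; features are centered and decomposed by SVD.
    Each component's sign is fixed by making its largest-magnitude loading
    positive, so coordinates are fully deterministic.  Returns
    ``(coords, variance_fractions)`` with coords indexed by library.
    """
    n_libs = log_matrix.shape[1]
    if n_libs < 2:
        raise ValueError("PCA needs at least 2 libraries")
    X = log_matrix.to_numpy(dtype=float).T  # libraries x loci
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    coords = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    var_frac = (S[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    coords_df = pd.DataFrame(
        coords, index=log_matrix.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return coords_df, var_frac


def log2_fold_change(matrix: CountMatrix, col_a: str, col_b: str, pseudocount: float = 1.0) -> pd.Series:
    """Naive per-locus log2 RPM ratio between two libraries.

    A descriptive contrast only — no dispersion model, no test; use a
    dedicated DE tool on the exported counts for inference.
    """
    rpm = matrix.rpm()
    return np.log2((rpm[col_a] + pseudocount) / (rpm[col_b] + pseudocount))


def export_counts(matrix: CountMatrix, path) -> None:
    """Integer counts as TSV (locus ids in the first column), plus the
    per-library totals as a trailing comment so RPM is reproducible."""
    with open(path, "w") as fh:
        totals = "\t".join(f"{n}={int(t)}" for n, t in matrix.totals.items())
        fh.write(f"# totals: {totals}\n")
        matrix.counts.to_csv(fh, sep="\t", index_label="locus_id")


def load_counts(path) -> CountMatrix:
    totals: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# totals:"):
            for tok in first.split(":", 1)[1].split():
                name, val = tok.split("=")
                totals[name] = int(val)
            df = pd.read_csv(fh, sep="\t", index_col="locus_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="locus_id")
    df = df.astype(np.int64)
    if not totals:
        totals = {c: int(df[c].sum()) for c in df.columns}
    return CountMatrix(counts=df, totals=pd.Series(totals, dtype=np.int64))
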