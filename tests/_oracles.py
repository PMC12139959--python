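"""Independent brute-force oracles for the signature scans.

All-pairs enumerations via numpy broadcasting over every (plus, minus) or
(upstream, downstream) read combination per chromosome — deliberately a
separate code path from the indexed/counting implementations in
``srnasig.signatures``.
"""

from collections import defaultdict

import numpy as np


def _by_chrom(library, strand=None):
    groups = defaultdict(list)
    for r in library:
        if strand is None or r.strand == strand:
            groups[r.chrom].append(r)
    return groups


def oracle_dicer_percent(library, pair_min_len=20, pair_max_len=24, overhang=2):
    plus = _by_chrom(library, "+")
    minus = _by_chrom(library, "-")
    members = 0
    for chrom in set(plus) | set(minus):
        p = [r for r in plus.get(chrom, []) if pair_min_len <= r.length <= pair_max_len]
        m = [r for r in minus.get(chrom, []) if pair_min_len <= r.length <= pair_max_len]
        if not p or not m:
            continue
        ps = np.array([r.start for r in p])[:, None]
        pe = np.array([r.end for r in p])[:, None]
        ms = np.array([r.start for r in m])[None, :]
        me = np.array([r.end for r in m])[None, :]
        pair = (ps - ms == overhang) & (pe - me == overhang)
        members += int(pair.any(axis=1).sum()) + int(pair.any(axis=0).sum())
    total = library.total_alignments
    if total == 0:
        raise ValueError("empty library")
    return 100.0 * members / total


def oracle_overlap_counts(library, max_overlap=30):
    plus = _by_chrom(library, "+")
    minus = _by_chrom(library, "-")
    counts = {o: 0 for o in range(1, max_overlap + 1)}
    for chrom in set(plus) & set(minus):
        p5 = np.array([r.five_prime for r in plus[chrom]])
        m5 = np.array([r.five_prime for r in minus[chrom]])
        o = m5[None, :] - p5[:, None] + 1
        vals, n = np.unique(o[(o >= 1) & (o <= max_overlap)], return_counts=True)
        for v, c in zip(vals, n):
            counts[int(v)] += int(c)
    return counts


def oracle_phasing_counts(library, max_dist=20, pairing="all"):
    counts = {d: 0 for d in range(1, max_dist + 1)}
    for strand in "+-":
        for chrom, group in _by_chrom(library, strand).items():
            u3 = np.array([r.end if strand == "+" else r.start for r in group])
            for w in group:
                if w.first_nt != "U":
                    continue
                # w itself always yields d <= 0, so no self-exclusion needed
                if strand == "+":
                    d = w.start - u3 + 1
                else:
                    d = u3 - w.end + 1
                if pairing == "nearest":
                    ok = d[d >= 1]
                    if ok.size == 0:
                        continue
                    dmin = int(ok.min())
                    if dmin <= max_dist:
                        counts[dmin] += 1
                else:
                    for v in d[(d >= 1) & (d <= max_dist)]:
                        counts[int(v)] += 1
    return counts
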