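"""Independent brute-force reference implementations used by the tests.

Every function here recomputes a pipeline quantity from first
principles (per-base walks, exhaustive enumeration, direct counting) so
the production code can be checked against an implementation that
shares none of its logic.
"""

from __future__ import annotations

import numpy as np


def walk_chain_base(chain, t_pos: int):
    """Map one source base by walking the chain's blocks one base at a time."""
    t = chain.t_start
    q = chain.q_start
    for size, dt, dq in chain.blocks:
        for _ in range(size):
            if t == t_pos:
                return chain.q_size - 1 - q if chain.q_strand == "-" else q
            t += 1
            q += 1
        if t_pos < t + dt and t <= t_pos:
            return None  # falls inside a source-side gap
        t += dt
        q += dq
    return None


def nw_best_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Optimal global alignment score by exhaustive recursion (len <= 8)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def brute_nearest_tss(locus, tss_list):
    """tss_list: (position0, gene_id). Mirrors the module's contract:
    sides split at the midpoint, distance measured to the interval."""
    mid = (locus.start + locus.end) // 2

    def dist(t):
        if t < locus.start:
            return locus.start - t
        if t >= locus.end:
            return t - locus.end + 1
        return 0

    up = [(dist(t), g) for t, g in tss_list if t <= mid]
    down = [(dist(t), g) for t, g in tss_list if t >= mid]
    return (min(up) if up else None, min(down) if down else None)


def brute_utr_overlap(locus, genes) -> bool:
    """Per-base scan over each gene's UTR and CDS segments."""
    positions = range(locus.start, locus.end)
    for g in genes.values():
        if g.chrom != locus.chrom:
            continue
        utr = set()
        cds = set()
        for tr in g.transcripts.values():
            for s, e in tr.utrs:
                utr.update(range(s, e))
            for s, e in tr.cds:
                cds.update(range(s, e))
        if not any(p in utr for p in positions):
            continue
        coding = sum(1 for p in positions if p in cds)
        if 3 * coding < 2 * len(locus):
            return True
    return False


def brute_hubs(edges_df, min_partners=10, min_dscore=0.5):
    adj: dict[str, set[str]] = {}
    for _, row in edges_df.iterrows():
        if row["dscore"] > min_dscore and row["gene_a"] != row["gene_b"]:
            adj.setdefault(row["gene_a"], set()).add(row["gene_b"])
            adj.setdefault(row["gene_b"], set()).add(row["gene_a"])
    return {g for g, p in adj.items() if len(p) > min_partners}


def leftmost_parsimonious(seq: str, pos: int, ref: str, alt: str):
    """Exhaustive search for the left-aligned parsimonious representation.

    Applies the variant to the reference, then enumerates every
    (position, ref-length) slice pair that reconstructs the same edited
    sequence; among valid representations the one with minimal total
    allele length, breaking ties leftmost, is the normal form.
    """
    hap = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    delta = len(hap) - len(seq)
    candidates = []
    for p in range(1, len(seq) + 1):
        for rl in range(0, 6):
            al = rl + delta
            if al < 0 or p - 1 + rl > len(seq):
                continue
            r = seq[p - 1 : p - 1 + rl]
            a = hap[p - 1 : p - 1 + al]
            if len(r) == 0 or len(a) == 0 or r == a:
                continue
            if seq[: p - 1] + a + seq[p - 1 + rl :] == hap:
                candidates.append((len(r) + len(a), p, r, a))
    assert candidates, "variant has no valid representation"
    _, p, r, a = min(candidates)
    return p, r, a


def consensus_from_labels(truth_genotypes, labels, callers):
    """Set-algebra pooled set derived purely from generator truth labels.

    Per sample: intersection over callers of (called truth sites minus
    false negatives minus low-quality calls, plus false positives);
    pooled: union over samples.
    """
    pooled = set()
    per_sample = {}
    for sample in truth_genotypes.index:
        sets = []
        for caller in callers:
            lab = labels[f"{sample}.{caller}"]
            called = {
                k for k in truth_genotypes.columns
                if truth_genotypes.loc[sample, k] > 0
            }
            called -= set(lab["fn"])
            called -= set(lab["low_qual"])
            called |= set(lab["fp"])
            sets.append(called)
        inter = set.intersection(*sets)
        per_sample[sample] = inter
        pooled |= inter
    return pooled, per_sample


def brute_carrier_filter(matrix, lo=11, hi=18):
    keep = []
    for col in matrix.columns:
        g = list(matrix[col])
        carriers = sum(1 for x in g if x > 0)
        others_ok = all(x == 0 for x in g if not x > 0)
        if lo <= carriers <= hi and others_ok:
            keep.append(col)
    return keep
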