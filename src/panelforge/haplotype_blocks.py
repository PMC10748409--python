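"""Haplotype-block estimation from unphased genotypes and proxy-SNP choice.

Blocks follow the Gabriel confidence-interval method as adopted by
Haploview and PLINK ``--blocks``: for each marker pair the likelihood of
the unphased genotype data is evaluated on a |D'| grid, giving a 90%
confidence interval; pairs are classified as "strong LD" or "strong
recombination"; a block is a marker run whose outermost pair is in
strong LD and whose informative pairs are almost all in strong LD.
Candidate loci are then represented on the panel by their nearest known
SNP, on the assumption that anything closer than the median block span
is likely in linkage with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval

EM_TOL = 1e-9
EM_MAX_ITER = 1000
DPRIME_GRID = np.round(np.arange(0, 1.001, 0.001), 3)


# ---------------------------------------------------------------------------
# genotype panel container


@dataclass
class GenotypePanel:
    """Unphased genotypes: subjects x markers, coded 0/1/2 (-1 = missing)."""

    chroms: list[str]
    positions: np.ndarray  # 1-based, per marker
    ids: list[str]
    genotypes: np.ndarray  # (n_subjects, n_markers) int8
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape[1] != len(self.positions):
            raise ValueError("genotype matrix does not match marker count")
        for c in set(self.chroms):
            idx = [i for i, x in enumerate(self.chroms) if x == c]
            if not all(
                self.positions[a] < self.positions[b]
                for a, b in zip(idx, idx[1:])
            ):
                raise ValueError(f"markers on {c} are not position-sorted")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


def panel_from_pedmap(ped_path, map_path) -> GenotypePanel:
    """Read PLINK text PED/MAP (alleles A=reference, G=alternate, 0=missing)."""
    chroms, ids, positions = [], [], []
    with open(map_path) as fh:
        for line in fh:
            c, i, _, p = line.split()
            chroms.append(c)
            ids.append(i)
            positions.append(int(p))
    rows, samples = [], []
    with open(ped_path) as fh:
        for line in fh:
            f = line.split()
            samples.append(f[1])
            alleles = f[6:]
            g = []
            for k in range(0, len(alleles), 2):
                a, b = alleles[k], alleles[k + 1]
                if a == "0" or b == "0":
                    g.append(-1)
                else:
                    g.append((a != "A") + (b != "A"))
            rows.append(g)
    return GenotypePanel(chroms, np.array(positions), ids, np.array(rows), samples)


def panel_from_vcf(vcf_path) -> GenotypePanel:
    import pysam

    chroms, ids, positions, cols = [], [], [], []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(-1)
                else:
                    col.append(sum(1 for a in gt if a != 0))
            cols.append(col)
    geno = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(samples), 0), np.int8)
    return GenotypePanel(chroms, np.array(positions), ids, geno, samples)


# ---------------------------------------------------------------------------
# two-locus EM and D'


@dataclass
class TwoLocusTable:
    """Estimated haplotype frequencies at two biallelic loci.

    ``p11`` is the frequency of the alt-alt haplotype, ``p10`` alt-ref,
    and so on; ``counts`` holds the observed 3x3 unphased genotype
    table that produced the estimate.
    """

    p11: float
    p10: float
    p01: float
    p00: float
    n_chromosomes: int
    counts: np.ndarray
    informative: bool = True

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00])


class MonomorphicError(ValueError):
    """Both-locus D' statistics need two polymorphic loci."""


def em_haplotypes(g1: np.ndarray, g2: np.ndarray) -> TwoLocusTable:
    """EM haplotype-frequency estimate from unphased two-locus genotypes.

    Only double heterozygotes have ambiguous phase; the E step splits
    them between the coupling and repulsion configurations, iterating
    from a uniform start until the frequency change is below 1e-9.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0) & (g2 >= 0)
    g1, g2 = g1[ok], g2[ok]
    if len(g1) < 2:
        raise ValueError("need at least 2 subjects with non-missing genotypes")
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1, g2), 1)
    informative = len(np.unique(g1)) > 1 and len(np.unique(g2)) > 1
    n_chrom = 2 * len(g1)

    # phase-known haplotype counts; haplotype order [11, 10, 01, 00]
    known = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # alleles at locus1: i copies of alt; haplotype alt-count split
            a1 = [1] * i + [0] * (2 - i)
            a2 = [1] * j + [0] * (2 - j)
            for h1, h2 in zip(a1, a2):
                known[(1 - h1) * 2 + (1 - h2)] += c
    n_dh = counts[1, 1]

    f = np.full(4, 0.25)
    for _ in range(EM_MAX_ITER):
        denom = f[0] * f[3] + f[1] * f[2]
        r = 0.5 if denom == 0 else f[0] * f[3] / denom
        exp_counts = known + n_dh * np.array([r, 1 - r, 1 - r, r])
        new = exp_counts / n_chrom
        if np.max(np.abs(new - f)) < EM_TOL:
            f = new
            break
        f = new
    return TwoLocusTable(f[0], f[1], f[2], f[3], n_chrom, counts, informative)


def dprime_point(table: TwoLocusTable) -> float:
    """|D'| from estimated haplotype frequencies."""
    pA = table.p11 + table.p10
    pB = table.p11 + table.p01
    D = table.p11 - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        raise MonomorphicError("monomorphic locus: D' undefined")
    return min(1.0, abs(D) / dmax)


@dataclass
class DprimeCI:
    dprime: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.ci_high <= 1):
            raise ValueError("CI bounds out of order")


def dprime_ci(table: TwoLocusTable) -> DprimeCI:
    """Likelihood-based 90% support interval for |D'| on a 0.001 grid.

    Allele frequencies are held at their sample estimates; the sign of D
    is absorbed by relabelling alleles at the second locus so that the
    grid covers D >= 0. ``ci_low``/``ci_high`` are the 5th and 95th
    percentiles of the normalized cumulative likelihood; ``dprime`` is
    the grid maximum-likelihood point.
    """
    if not table.informative:
        raise MonomorphicError("monomorphic locus: D' undefined")
    counts = table.counts.astype(float)
    n = counts.sum()
    # observed allele (alt) frequencies
    pA = (counts.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pB = (counts.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    D = table.p11 - pA * pB
    if D < 0:
        counts = counts[:, ::-1]
        pB = 1 - pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    if dmax <= 0:
        raise MonomorphicError("monomorphic locus: D' undefined")

    d_grid = DPRIME_GRID
    Dg = d_grid * dmax
    p11 = np.clip(pA * pB + Dg, 1e-12, None)
    p10 = np.clip(pA * (1 - pB) - Dg, 1e-12, None)
    p01 = np.clip((1 - pA) * pB - Dg, 1e-12, None)
    p00 = np.clip((1 - pA) * (1 - pB) + Dg, 1e-12, None)
    probs = np.stack(
        [
            p00 ** 2, 2 * p00 * p01, p01 ** 2,
            2 * p00 * p10, 2 * (p11 * p00 + p10 * p01), 2 * p01 * p11,
            p10 ** 2, 2 * p10 * p11, p11 ** 2,
        ]
    )  # rows: genotype combos (g1,g2) in row-major order
    ll = counts.reshape(9) @ np.log(probs)
    w = np.exp(ll - ll.max())
    cum = np.cumsum(w) / w.sum()
    ci_low = float(d_grid[np.searchsorted(cum, 0.05)])
    ci_high = float(d_grid[np.searchsorted(cum, 0.95)])
    point = float(d_grid[int(np.argmax(ll))])
    point = min(max(point, ci_low), ci_high)
    return DprimeCI(point, ci_low, ci_high)


# ---------------------------------------------------------------------------
# Gabriel blocks


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    first_snp_index: int  # indices into the panel's marker order
    last_snp_index: int
    span_bp: int

    def __post_init__(self) -> None:
        if self.last_snp_index <= self.first_snp_index:
            raise ValueError("a block needs at least two markers")


@dataclass
class GabrielParams:
    strong_low: float = 0.70
    strong_high: float = 0.98
    recomb_high: float = 0.90
    informative_fraction: float = 0.95
    max_span_kb: float = 200.0


STRONG, RECOMB, UNINFORMATIVE = 1, 0, -1


def classify_pair(g1: np.ndarray, g2: np.ndarray, params: GabrielParams) -> int:
    try:
        ci = dprime_ci(em_haplotypes(g1, g2))
    except (MonomorphicError, ValueError):
        return UNINFORMATIVE
    if ci.ci_low >= params.strong_low and ci.ci_high >= params.strong_high:
        return STRONG
    if ci.ci_high < params.recomb_high:
        return RECOMB
    return UNINFORMATIVE


def find_blocks(
    panel: GenotypePanel, params: GabrielParams | None = None
) -> list[HaplotypeBlock]:
    """Gabriel-criteria block detection, greedy longest-span-first.

    A candidate block's outermost marker pair must be in strong LD and
    at least ``informative_fraction`` of its informative pairs must be
    in strong LD; candidates are accepted longest span first, skipping
    any that overlap an accepted block.
    """
    params = params or GabrielParams()
    max_span = int(params.max_span_kb * 1000)
    blocks: list[HaplotypeBlock] = []
    for chrom in sorted(set(panel.chroms)):
        idx = [i for i, c in enumerate(panel.chroms) if c == chrom]
        m = len(idx)
        if m < 2:
            continue
        pos = panel.positions[idx]
        cls = np.full((m, m), UNINFORMATIVE, dtype=np.int8)
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] + 1 > max_span:
                    break
                cls[a, b] = classify_pair(
                    panel.genotypes[:, idx[a]], panel.genotypes[:, idx[b]], params
                )
        candidates = []
        for a in range(m):
            for b in range(a + 1, m):
                span = int(pos[b] - pos[a] + 1)
                if span > max_span:
                    break
                if cls[a, b] != STRONG:
                    continue
                sub = cls[a : b + 1, a : b + 1]
                n_strong = int((sub == STRONG).sum())
                n_recomb = int((sub == RECOMB).sum())
                informative = n_strong + n_recomb
                if informative == 0:
                    continue
                if n_strong / informative >= params.informative_fraction:
                    candidates.append((span, a, b))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(m, dtype=bool)
        for span, a, b in candidates:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            blocks.append(HaplotypeBlock(chrom, idx[a], idx[b], span))
    return sorted(blocks, key=lambda b: (b.chrom, b.first_snp_index))


def median_block_span(blocks: list[HaplotypeBlock]) -> float:
    if not blocks:
        raise ValueError("no blocks detected")
    return float(np.median([b.span_bp for b in blocks]))


def blocks_table(panel: GenotypePanel, blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start": int(panel.positions[b.first_snp_index]),
                "end": int(panel.positions[b.last_snp_index]),
                "n_snps": b.last_snp_index - b.first_snp_index + 1,
                "span_bp": b.span_bp,
            }
            for b in blocks
        ],
        columns=["chrom", "start", "end", "n_snps", "span_bp"],
    )


# ---------------------------------------------------------------------------
# proxy-SNP assignment


@dataclass
class ProxyAssignment:
    proxy_rsid: str
    proxy_chrom: str
    proxy_pos: int  # 1-based
    represented_loci: list[str]
    distance_bp: int  # smallest distance over represented loci
    within_median_block: bool


def assign_proxies(
    loci: list[tuple[str, GenomicInterval]],
    known_snps: pd.DataFrame,
    median_span_bp: float,
) -> tuple[list[ProxyAssignment], list[str]]:
    """Represent each locus by its nearest known SNP, merged per SNP.

    ``known_snps`` needs columns ``rsid chrom pos`` (1-based). Ties in
    distance break to the lower coordinate. Loci sharing a nearest SNP
    are merged into a single assignment, so the output has one entry per
    unique proxy. Returns (assignments, names of unassignable loci).
    """
    by_chrom: dict[str, pd.DataFrame] = {
        c: df.sort_values("pos") for c, df in known_snps.groupby("chrom")
    }
    chosen: dict[str, dict] = {}
    unassigned: list[str] = []
    for name, locus in loci:
        cands = by_chrom.get(locus.chrom)
        if cands is None or cands.empty:
            unassigned.append(name)
            continue
        dists = [
            (locus.distance_to_point(int(p) - 1), int(p), str(r))
            for r, p in cands[["rsid", "pos"]].itertuples(index=False)
        ]
        d, p, rsid = min(dists)
        entry = chosen.setdefault(
            rsid, {"chrom": locus.chrom, "pos": p, "loci": [], "dist": d}
        )
        entry["loci"].append(name)
        entry["dist"] = min(entry["dist"], d)
    assignments = [
        ProxyAssignment(
            rsid,
            e["chrom"],
            e["pos"],
            sorted(e["loci"]),
            e["dist"],
            e["dist"] < median_span_bp,
        )
        for rsid, e in sorted(chosen.items(), key=lambda kv: (kv[1]["chrom"], kv[1]["pos"]))
    ]
    return assignments, unassigned


def proxies_table(assignments: list[ProxyAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rsid": a.proxy_rsid,
                "chrom": a.proxy_chrom,
                "pos": a.proxy_pos,
                "represented_loci": ",".join(a.represented_loci),
                "distance_bp": a.distance_bp,
                "within_median_block": a.within_median_block,
            }
            for a in assignments
        ],
        columns=[
            "rsid", "chrom", "pos",
            "represented_loci", "distance_bp", "within_median_block",
        ],
    )
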