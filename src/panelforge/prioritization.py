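"""Functional prioritization of candidate loci.

Loci are promoted to the panel when they (a) overlap a UTR without
substantial coding-exon overlap, (b) have a transcription-factor gene as
nearest upstream or downstream TSS, (c) fall inside a designated
key-regulator gene, or (d) have a differentially expressed network-hub
gene as nearest TSS. Each locus is reported once, with every reason
that applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd

from .core import GenomicInterval


# ---------------------------------------------------------------------------
# gene models


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    cds: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def tss(self, strand: str) -> int:
        """0-based position of the transcript 5' end, strand-aware."""
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo if strand == "+" else hi - 1


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def tss_positions(self) -> list[int]:
        return [t.tss(self.strand) for t in self.transcripts.values() if t.exons]


def read_gene_models(gtf_path) -> dict[str, GeneModel]:
    """Load gene models from a GTF file (gffutils in-memory db)."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        name = g.attributes.get("gene_name", [gid])[0]
        genes[gid] = GeneModel(gid, name, g.seqid, g.strand, g.start - 1, g.end)
    for t in db.features_of_type("transcript"):
        gid = t.attributes["gene_id"][0]
        tid = t.attributes["transcript_id"][0]
        genes[gid].transcripts[tid] = Transcript(tid)
    for ftype, attr in (
        ("exon", "exons"),
        ("CDS", "cds"),
        ("five_prime_utr", "utrs"),
        ("three_prime_utr", "utrs"),
    ):
        for f in db.features_of_type(ftype):
            gid = f.attributes["gene_id"][0]
            tid = f.attributes["transcript_id"][0]
            tr = genes[gid].transcripts.setdefault(tid, Transcript(tid))
            getattr(tr, attr).append((f.start - 1, f.end))
    for g in genes.values():
        for tr in g.transcripts.values():
            tr.exons.sort()
            tr.cds.sort()
            tr.utrs.sort()
    return genes


def filter_annotation(
    genes: dict[str, GeneModel], min_feature_len: int = 51, drop_short: bool = True
) -> dict[str, GeneModel]:
    """Remove sub-gene features shorter than ``min_feature_len``.

    Features covering ``min_feature_len - 1`` bp or less (default: 50 bp
    or less) are dropped before any overlap computation. Set
    ``drop_short=False`` to keep the annotation untouched.
    """
    if not drop_short:
        return genes
    out: dict[str, GeneModel] = {}
    for gid, g in genes.items():
        ng = GeneModel(g.gene_id, g.gene_name, g.chrom, g.strand, g.start, g.end)
        for tid, tr in g.transcripts.items():
            keep = lambda segs: [(s, e) for s, e in segs if e - s >= min_feature_len]
            ng.transcripts[tid] = Transcript(
                tid, keep(tr.exons), keep(tr.cds), keep(tr.utrs)
            )
        out[gid] = ng
    return out


# ---------------------------------------------------------------------------
# per-locus predicates


def _union_overlap(locus: GenomicInterval, segs: list[tuple[int, int]]) -> int:
    """Total overlap of the locus with the union of segments."""
    events = sorted(segs)
    total = 0
    cur_s, cur_e = None, None
    for s, e in events:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += max(0, min(cur_e, locus.end) - max(cur_s, locus.start))
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += max(0, min(cur_e, locus.end) - max(cur_s, locus.start))
    return total


def overlaps_utr(locus: GenomicInterval, genes: dict[str, GeneModel]) -> bool:
    """True iff the locus lies in a UTR with < 2/3 of its length coding.

    For every gene whose UTR the locus touches, the locus qualifies when
    the coding exons of that gene (union over transcripts) cover
    strictly less than two thirds of the locus length.
    """
    for g in genes.values():
        if g.chrom != locus.chrom:
            continue
        utr_hit = any(
            min(e, locus.end) > max(s, locus.start)
            for tr in g.transcripts.values()
            for s, e in tr.utrs
        )
        if not utr_hit:
            continue
        cds_segs = [seg for tr in g.transcripts.values() for seg in tr.cds]
        coding_overlap = _union_overlap(locus, cds_segs)
        if 3 * coding_overlap < 2 * len(locus):
            return True
    return False


@dataclass
class NearestTss:
    upstream_gene: str | None
    upstream_distance: int | None
    downstream_gene: str | None
    downstream_distance: int | None

    @property
    def nearest_gene(self) -> str | None:
        """The closer of the two flanking TSS genes (tie: upstream)."""
        cands = [
            (d, g)
            for d, g in (
                (self.upstream_distance, self.upstream_gene),
                (self.downstream_distance, self.downstream_gene),
            )
            if g is not None
        ]
        if not cands:
            return None
        return min(cands, key=lambda x: (x[0], x[1]))[1]

    @property
    def nearest_distance(self) -> int | None:
        dists = [
            d
            for d in (self.upstream_distance, self.downstream_distance)
            if d is not None
        ]
        return min(dists) if dists else None


def nearest_tss(locus: GenomicInterval, genes: dict[str, GeneModel]) -> NearestTss:
    """Nearest TSS on each side of the locus midpoint.

    Distances are to the locus itself (0 when the TSS falls inside it);
    ties break to the lexicographically smaller gene_id.
    """
    mid = locus.midpoint
    up: list[tuple[int, str]] = []
    down: list[tuple[int, str]] = []
    for g in genes.values():
        if g.chrom != locus.chrom:
            continue
        for tss in g.tss_positions():
            d = locus.distance_to_point(tss)
            if tss <= mid:
                up.append((d, g.gene_id))
            if tss >= mid:
                down.append((d, g.gene_id))
    if not up and not down:
        warnings.warn(f"no TSS on chromosome {locus.chrom}")
    ug = min(up) if up else None
    dg = min(down) if down else None
    return NearestTss(
        ug[1] if ug else None,
        ug[0] if ug else None,
        dg[1] if dg else None,
        dg[0] if dg else None,
    )


def hub_genes(
    edges: pd.DataFrame, min_partners: int = 10, min_dscore: float = 0.5
) -> set[str]:
    """Genes with more than ``min_partners`` distinct interaction partners.

    Only edges whose curated-evidence score ("dscore") exceeds
    ``min_dscore`` count; self-loops and duplicate edges are ignored.
    Both thresholds are strict.
    """
    partners: dict[str, set[str]] = {}
    for a, b, d in edges[["gene_a", "gene_b", "dscore"]].itertuples(index=False):
        if not d > min_dscore or a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return {g for g, p in partners.items() if len(p) > min_partners}


def tf_genes_from_table(tf_class_table: pd.DataFrame) -> set[str]:
    """Gene ids whose protein class marks them as transcription factors."""
    mask = tf_class_table["protein_class"].str.contains(
        "transcription factor", case=False, na=False
    )
    return set(tf_class_table.loc[mask, "gene_id"])


# ---------------------------------------------------------------------------
# combined selection


@dataclass
class PrioritizedLocus:
    name: str
    locus: GenomicInterval
    reasons: frozenset
    nearest_gene: str | None
    nearest_tss_distance: int | None

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("a prioritized locus needs at least one reason")


def prioritize(
    loci: list[tuple[str, GenomicInterval]],
    genes: dict[str, GeneModel],
    tf_class_table: pd.DataFrame | None,
    deg_genes: set[str],
    key_regulator_genes: set[str],
    edges: pd.DataFrame,
    min_partners: int = 10,
    min_dscore: float = 0.5,
) -> list[PrioritizedLocus]:
    """Union of the four selection criteria with complete reason tags."""
    if tf_class_table is None:
        warnings.warn("no protein-class table: TF-proximity criterion skipped")
        tf_set: set[str] = set()
    else:
        tf_set = tf_genes_from_table(tf_class_table)
    hubs = hub_genes(edges, min_partners, min_dscore)
    selected: list[PrioritizedLocus] = []
    for name, locus in loci:
        nt = nearest_tss(locus, genes)
        reasons = set()
        if overlaps_utr(locus, genes):
            reasons.add("utr")
        if (nt.upstream_gene in tf_set) or (nt.downstream_gene in tf_set):
            reasons.add("tf_proximal")
        if any(
            locus.overlaps(genes[g].span)
            for g in key_regulator_genes
            if g in genes
        ):
            reasons.add("key_regulator")
        ng = nt.nearest_gene
        if ng is not None and ng in deg_genes and ng in hubs:
            reasons.add("deg_hub")
        if reasons:
            selected.append(
                PrioritizedLocus(
                    name, locus, frozenset(reasons), ng, nt.nearest_distance
                )
            )
    return selected


def prioritized_table(selected: list[PrioritizedLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": p.name,
                "chrom": p.locus.chrom,
                "start": p.locus.start + 1,
                "end": p.locus.end,
                "reasons": ",".join(sorted(p.reasons)),
                "nearest_gene": p.nearest_gene or "",
                "nearest_tss_distance": (
                    -1 if p.nearest_tss_distance is None else p.nearest_tss_distance
                ),
            }
            for p in selected
        ],
        columns=[
            "name", "chrom", "start", "end",
            "reasons", "nearest_gene", "nearest_tss_distance",
        ],
    )
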