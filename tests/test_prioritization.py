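import numpy as np
import pandas as pd
import pytest

from panelforge.core import GenomicInterval
from panelforge.prioritization import (
    GeneModel,
    Transcript,
    filter_annotation,
    hub_genes,
    nearest_tss,
    overlaps_utr,
    prioritize,
    tf_genes_from_table,
)

from oracles import brute_hubs, brute_nearest_tss, brute_utr_overlap


def gene(gene_id, chrom, strand, transcripts):
    segs = [seg for tr in transcripts.values()
            for group in (tr.exons, tr.cds, tr.utrs) for seg in group]
    g = GeneModel(gene_id, gene_id, chrom, strand,
                  min(s for s, _ in segs), max(e for _, e in segs))
    g.transcripts = transcripts
    return g


def simple_gene(gene_id, chrom, strand, exon, cds=(), utrs=()):
    tr = Transcript(gene_id + ".t1", [exon], list(cds), list(utrs))
    return gene(gene_id, chrom, strand, {tr.transcript_id: tr})


class TestAnnotationFilter:
    def test_length_boundary_50_removed_51_kept(self):
        g = simple_gene("g1", "chr1", "+", (0, 500),
                        cds=[(0, 50), (100, 151)], utrs=[(200, 250), (300, 352)])
        out = filter_annotation({"g1": g})["g1"].transcripts["g1.t1"]
        assert out.cds == [(100, 151)]
        assert out.utrs == [(300, 352)]

    def test_no_short_features_is_identity(self):
        g = simple_gene("g1", "chr1", "+", (0, 500), cds=[(0, 100)])
        out = filter_annotation({"g1": g})["g1"].transcripts["g1.t1"]
        assert out.cds == [(0, 100)] and out.exons == [(0, 500)]

    def test_matches_brute_force_length_filter(self, rng):
        segs = [(int(s), int(s) + int(l)) for s, l in
                zip(rng.integers(0, 5000, 50), rng.integers(1, 120, 50))]
        g = simple_gene("g1", "chr1", "+", (0, 6000), cds=segs)
        out = filter_annotation({"g1": g})["g1"].transcripts["g1.t1"]
        assert sorted(out.cds) == sorted(s for s in segs if s[1] - s[0] >= 51)


class TestUtrOverlap:
    def test_locus_inside_utr_without_coding(self):
        g = simple_gene("g1", "chr1", "+", (0, 1000), utrs=[(100, 400)])
        assert overlaps_utr(GenomicInterval("chr1", 150, 250), {"g1": g})

    def test_two_thirds_coding_boundary_is_strict(self):
        # 99-bp locus: 66 bp coding overlap (exactly 2/3) disqualifies,
        # 65 bp qualifies
        locus = GenomicInterval("chr1", 0, 99)
        g66 = simple_gene("g1", "chr1", "+", (0, 500),
                          cds=[(0, 66)], utrs=[(66, 200)])
        g65 = simple_gene("g1", "chr1", "+", (0, 500),
                          cds=[(0, 65)], utrs=[(65, 200)])
        assert not overlaps_utr(locus, {"g1": g66})
        assert overlaps_utr(locus, {"g1": g65})

    def test_matches_per_base_oracle(self, rng):
        for _ in range(100):
            genes = {}
            for k in range(3):
                utrs = [(int(s), int(s + rng.integers(20, 200)))
                        for s in rng.integers(0, 2000, 2)]
                cds = [(int(s), int(s + rng.integers(20, 200)))
                       for s in rng.integers(0, 2000, 2)]
                g = simple_gene(f"g{k}", "chr1", "+", (0, 3000),
                                cds=cds, utrs=utrs)
                genes[f"g{k}"] = g
            s = int(rng.integers(0, 1900))
            locus = GenomicInterval("chr1", s, s + int(rng.integers(30, 150)))
            assert overlaps_utr(locus, genes) == brute_utr_overlap(locus, genes)


class TestNearestTss:
    def test_flanking_tss_distances(self):
        genes = {
            "a": simple_gene("a", "chr1", "+", (900, 1200)),
            "b": simple_gene("b", "chr1", "+", (1400, 1800)),
        }
        locus = GenomicInterval("chr1", 1000, 1100)
        nt = nearest_tss(locus, genes)
        assert nt.upstream_gene == "a" and nt.upstream_distance == 100
        assert nt.downstream_gene == "b" and nt.downstream_distance == 301

    def test_tss_inside_locus_has_distance_zero(self):
        genes = {"a": simple_gene("a", "chr1", "+", (1050, 1500))}
        nt = nearest_tss(genes=genes, locus=GenomicInterval("chr1", 1000, 1100))
        assert nt.upstream_distance == 0 or nt.downstream_distance == 0

    def test_chromosome_without_genes_flags(self):
        genes = {"a": simple_gene("a", "chr2", "+", (0, 100))}
        with pytest.warns(UserWarning, match="no TSS"):
            nt = nearest_tss(GenomicInterval("chr1", 10, 60), genes)
        assert nt.upstream_gene is None and nt.downstream_gene is None

    def test_matches_brute_force_scan(self, rng):
        for _ in range(100):
            genes = {}
            tss_list = []
            for k in range(int(rng.integers(1, 8))):
                strand = "+" if rng.random() < 0.5 else "-"
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(60, 400))
                g = simple_gene(f"g{k:02d}", "chr1", strand, (s, e))
                genes[g.gene_id] = g
                tss_list.append((s if strand == "+" else e - 1, g.gene_id))
            a = int(rng.integers(0, 4800))
            locus = GenomicInterval("chr1", a, a + int(rng.integers(20, 150)))
            nt = nearest_tss(locus, genes)
            up, down = brute_nearest_tss(locus, tss_list)
            assert (nt.upstream_distance, nt.upstream_gene) == up or up is None
            assert (nt.downstream_distance, nt.downstream_gene) == down or down is None


class TestHubs:
    def test_partner_count_boundary_is_strict(self):
        rows = [{"gene_a": "hub", "gene_b": f"p{i}", "dscore": 0.8}
                for i in range(10)]
        ten = pd.DataFrame(rows)
        eleven = pd.DataFrame(
            rows + [{"gene_a": "hub", "gene_b": "p10", "dscore": 0.8}]
        )
        assert "hub" not in hub_genes(ten)
        assert "hub" in hub_genes(eleven)

    def test_duplicate_edges_and_low_dscore_do_not_count(self):
        rows = [{"gene_a": "hub", "gene_b": f"p{i}", "dscore": 0.8}
                for i in range(11)]
        dup = pd.DataFrame(rows + rows[:5])
        assert "hub" in hub_genes(dup)
        weak = pd.DataFrame(
            [dict(r, dscore=0.5) for r in rows]  # dscore must exceed 0.5
        )
        assert hub_genes(weak) == set()

    def test_matches_brute_force_adjacency(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            rows = [
                {"gene_a": f"g{rng.integers(0, n)}",
                 "gene_b": f"g{rng.integers(0, n)}",
                 "dscore": float(rng.random())}
                for _ in range(int(rng.integers(10, 120)))
            ]
            edges = pd.DataFrame(rows)
            assert hub_genes(edges, 3, 0.5) == brute_hubs(edges, 3, 0.5)


class TestPrioritize:
    def test_planted_composition_yields_101(self, design_chain):
        selected = design_chain["selected"]
        assert len(selected) == 101
        got = {p.name: p.reasons for p in selected}
        assert got == design_chain["pfx"].expected_reasons

    def test_reason_tags_are_rederivable(self, design_chain):
        genes = design_chain["genes"]
        tf_set = tf_genes_from_table(design_chain["pfx"].tf_class_table)
        for p in list(design_chain["selected"])[::10]:
            if "utr" in p.reasons:
                assert overlaps_utr(p.locus, genes)
            if "tf_proximal" in p.reasons:
                nt = nearest_tss(p.locus, genes)
                assert nt.upstream_gene in tf_set or nt.downstream_gene in tf_set

    def test_no_qualifying_loci_yields_empty(self):
        genes = {"a": simple_gene("a", "chr1", "+", (0, 100))}
        out = prioritize(
            [("l1", GenomicInterval("chr1", 5000, 5100))], genes,
            pd.DataFrame(columns=["gene_id", "protein_class"]),
            set(), set(), pd.DataFrame(columns=["gene_a", "gene_b", "dscore"]),
        )
        assert out == []

    def test_missing_class_table_skips_tf_criterion(self):
        genes = {"a": simple_gene("a", "chr1", "+", (0, 100))}
        with pytest.warns(UserWarning, match="class table"):
            out = prioritize(
                [("l1", GenomicInterval("chr1", 10, 60))], genes, None,
                set(), set(), pd.DataFrame(columns=["gene_a", "gene_b", "dscore"]),
            )
        assert out == []

    def test_selection_monotone_in_edges(self, rng):
        # adding an interaction edge never removes a selected locus
        genes = {"hub": simple_gene("hub", "chr1", "+", (40, 400))}
        locus = [("l1", GenomicInterval("chr1", 10, 110))]
        rows = [{"gene_a": "hub", "gene_b": f"p{i}", "dscore": 0.9}
                for i in range(11)]
        base = prioritize(locus, genes, None, {"hub"}, set(), pd.DataFrame(rows))
        more = prioritize(
            locus, genes, None, {"hub"}, set(),
            pd.DataFrame(rows + [{"gene_a": "hub", "gene_b": "x", "dscore": 0.9}]),
        )
        assert {p.name for p in base} <= {p.name for p in more}
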