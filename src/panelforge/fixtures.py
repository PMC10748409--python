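"""Composed fixtures built from the synthetic generators.

These builders wire the primitive generators into bundles whose filter
cascades provably produce chosen class sizes: an annotation/network
bundle in which an exact subset of loci qualifies for prioritization,
and a full 29-sample cohort (reference, target windows, three caller
VCFs per sample, survival table) with planted carrier counts, duplicate
genotype patterns, and hazard effects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .consensus import Variant, variant_key
from .core import GenomicInterval
from .synthetic_data import (
    _random_seq,
    simulate_caller_vcfs,
    simulate_survival,
    write_fasta,
    write_truth,
)

# ---------------------------------------------------------------------------
# prioritization fixture


@dataclass
class PrioritizationFixture:
    gtf_text: str
    tf_class_table: pd.DataFrame
    deg_genes: set[str]
    key_regulator_genes: set[str]
    edges: pd.DataFrame
    expected_reasons: dict[str, frozenset]  # locus name -> reason tags

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.gtf_text)


def _gtf_line(chrom, feature, start0, end, strand, gene_id, transcript_id=None):
    attrs = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
    if transcript_id:
        attrs += f' transcript_id "{transcript_id}";'
    return (
        f"{chrom}\tsynthetic\t{feature}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
    )


def make_prioritization_fixture(
    loci: list[tuple[str, GenomicInterval]],
    n_utr: int = 29,
    n_tf: int = 48,
    n_key: int = 4,
    n_hub: int = 29,
    n_overlap: int = 9,
    hub_partners: int = 12,
) -> PrioritizationFixture:
    """Annotation/network bundle selecting an exact locus subset.

    The first ``n_utr`` loci get UTR-overlapping genes (the first
    ``n_overlap`` of those genes are additionally classed as
    transcription factors, creating utr+tf dual tags); the next
    ``n_tf - n_overlap`` loci get TF genes at their nearest TSS; the
    next ``n_key`` loci fall inside one shared key-regulator gene; the
    next ``n_hub`` loci get differentially expressed hub genes. All
    remaining loci receive an inert filler gene so that their nearest
    TSS qualifies for nothing. Unique selected loci:
    ``n_utr + n_tf + n_key + n_hub - n_overlap``.
    """
    if n_overlap > min(n_utr, n_tf):
        raise ValueError("more planted overlaps than UTR/TF loci")
    n_selected = n_utr + (n_tf - n_overlap) + n_key + n_hub
    if n_selected > len(loci):
        raise ValueError(f"need at least {n_selected} loci, got {len(loci)}")
    loci = sorted(loci, key=lambda x: (x[1].chrom, x[1].start))

    lines: list[str] = []
    tf_rows: list[dict] = []
    deg: set[str] = set()
    keyset: set[str] = set()
    edge_rows: list[dict] = []
    expected: dict[str, frozenset] = {}

    i_utr = range(0, n_utr)
    i_tf = range(n_utr, n_utr + n_tf - n_overlap)
    i_key = range(i_tf.stop, i_tf.stop + n_key)
    i_hub = range(i_key.stop, i_key.stop + n_hub)

    def add_gene(chrom, strand, gene_id, *transcripts):
        """Each transcript is a list of (feature, start0, end) segments."""
        lo = min(s for t in transcripts for _, s, _ in t)
        hi = max(e for t in transcripts for _, _, e in t)
        lines.append(_gtf_line(chrom, "gene", lo, hi, strand, gene_id))
        for k, segments in enumerate(transcripts, start=1):
            tid = f"{gene_id}.t{k}"
            tlo = min(s for _, s, _ in segments)
            thi = max(e for _, _, e in segments)
            lines.append(_gtf_line(chrom, "transcript", tlo, thi, strand, gene_id, tid))
            for feature, s, e in segments:
                lines.append(_gtf_line(chrom, feature, s, e, strand, gene_id, tid))

    for idx, (name, locus) in enumerate(loci):
        chrom, s, e = locus.chrom, locus.start, locus.end
        mid = locus.midpoint
        if idx in i_utr:
            g = f"UTRG{idx:04d}"
            # second transcript's TSS sits inside the locus so the gene
            # is its own nearest TSS on both sides
            add_gene(chrom, "+", g, [
                ("exon", s - 10, e + 70),
                ("three_prime_utr", s - 10, e + 10),
                ("CDS", e + 10, e + 70),
            ], [("exon", mid, mid + 200)])
            reasons = {"utr"}
            if idx < n_overlap:
                tf_rows.append({"gene_id": g, "protein_class": "transcription factor"})
                reasons.add("tf_proximal")
            expected[name] = frozenset(reasons)
        elif idx in i_tf:
            g = f"TFG{idx:04d}"
            add_gene(chrom, "+", g, [("exon", mid, mid + 200)])
            tf_rows.append({"gene_id": g, "protein_class": "transcription factor"})
            expected[name] = frozenset({"tf_proximal"})
        elif idx in i_key:
            if idx == i_key.start:
                g = "KEYG0001"
                span_end = loci[i_key.stop - 1][1].end + 50
                add_gene(chrom, "+", g, [("exon", s - 50, span_end)])
                keyset.add(g)
            # an inert gene wins the nearest-TSS contest for key loci
            add_gene(chrom, "+", f"FILLG{idx:04d}", [("exon", mid, mid + 150)])
            expected[name] = frozenset({"key_regulator"})
        elif idx in i_hub:
            g = f"HUBG{idx:04d}"
            add_gene(chrom, "+", g, [("exon", mid, mid + 200)])
            deg.add(g)
            for k in range(hub_partners):
                edge_rows.append(
                    {"gene_a": g, "gene_b": f"P{idx:04d}_{k:02d}",
                     "dscore": round(0.6 + 0.02 * (k % 15), 2)}
                )
            expected[name] = frozenset({"deg_hub"})
        else:
            add_gene(chrom, "+", f"FILLG{idx:04d}", [("exon", mid, mid + 150)])

    return PrioritizationFixture(
        "\n".join(lines) + "\n",
        pd.DataFrame(tf_rows, columns=["gene_id", "protein_class"]),
        deg,
        keyset,
        pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "dscore"]),
        expected,
    )


def make_known_snp_map(
    loci: list[tuple[str, GenomicInterval]],
    max_pair_gap: int = 400,
) -> pd.DataFrame:
    """Known-SNP catalog in which exactly two loci share a nearest SNP.

    Every locus gets its own known SNP 40-99 bp past its end — closer
    than any neighbouring locus's SNP — except for one adjacent pair
    (the first pair closer than ``max_pair_gap``), which is covered by
    a single SNP midway between the two. Unique nearest SNPs:
    ``len(loci) - 1``.
    """
    loci = sorted(loci, key=lambda x: (x[1].chrom, x[1].start))
    shared = None
    for i in range(len(loci) - 1):
        a, b = loci[i][1], loci[i + 1][1]
        if a.chrom == b.chrom and b.start - a.end <= max_pair_gap:
            shared = i
            break
    if shared is None:
        raise ValueError(f"no adjacent locus pair within {max_pair_gap} bp")
    rows = []
    for i, (_, locus) in enumerate(loci):
        if i == shared:
            mid = (locus.end + loci[i + 1][1].start) // 2
            rows.append({"rsid": f"can{i:04d}", "chrom": locus.chrom, "pos": mid + 1})
        elif i == shared + 1:
            continue
        else:
            off = 40 + (i * 13) % 60
            rows.append(
                {"rsid": f"can{i:04d}", "chrom": locus.chrom, "pos": locus.end + off}
            )
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])


# ---------------------------------------------------------------------------
# cohort fixture (consensus + survival)

TARGET_LEN = 300
TARGET_SPACING = 800
RUN_OFFSET = 200  # homopolymer run offset within a target
RUN_LEN = 6


@dataclass
class CohortFixture:
    reference: dict[str, str]
    target_bed: pd.DataFrame  # chrom start end name (0-based half-open)
    truth_variants: pd.DataFrame  # chrom pos ref alt key target_id
    genotypes: pd.DataFrame  # samples x variant_key
    survival: pd.DataFrame  # sample time event endpoint + covariates
    truth: dict
    vcf_dir: str | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)

    def write(self, out_dir, config: SimulationConfig) -> None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(os.path.join(out_dir, "reference.fa"), self.reference)
        self.target_bed.to_csv(
            os.path.join(out_dir, "targets.bed"), sep="\t", index=False, header=False
        )
        self.survival.to_csv(os.path.join(out_dir, "survival.tsv"), sep="\t")
        vcf_dir = os.path.join(out_dir, "vcf")
        simulate_caller_vcfs(
            self.reference,
            self.truth_variants[["chrom", "pos", "ref", "alt"]],
            self.genotypes,
            config,
            vcf_dir,
            rng=np.random.default_rng(config.seed + 77),
        )
        self.vcf_dir = vcf_dir
        write_truth(out_dir, self.truth)


def make_cohort_fixture(
    n_samples: int = 29,
    seed: int = 0,
    polymorphic_carrier_counts: tuple[int, ...] = (11, 12, 13, 14, 15, 16, 17, 18, 11, 13),
    planted_beta: tuple[float, float] = (np.log(2), -np.log(2)),
    censor_fraction: float = 7 / 29,
) -> CohortFixture:
    """Cohort with known pooled variants, duplicate patterns, and effects.

    Ten base variants carry the given cohort carrier counts (all within
    the 11-18 polymorphism band); the first two each get a same-target
    duplicate with an identical genotype vector, for 12 cohort-
    polymorphic variants collapsing to 10. Four further variants fall
    outside the band (1, 5, 20 and all-subject carriers). The survival
    table plants a harmful and a protective hazard effect on the first
    two base variants; remaining covariates (sex, neuter status, WHO
    stage, protocol, age) are effect-free.
    """
    rng = np.random.default_rng(seed)
    n_targets = 14
    chrom = "chr1"
    seq = list(_random_seq(rng, 500 + n_targets * TARGET_SPACING + 500))
    bed_rows = []
    target_start = {}
    for k in range(n_targets):
        ts = 500 + k * TARGET_SPACING
        target_start[k] = ts
        # plant a clean homopolymer run: C AAAAAA G
        r = ts + RUN_OFFSET
        seq[r - 1] = "C"
        for j in range(RUN_LEN):
            seq[r + j] = "A"
        seq[r + RUN_LEN] = "G"
        bed_rows.append(
            {"chrom": chrom, "start": ts, "end": ts + TARGET_LEN, "name": f"target_{k:02d}"}
        )
    reference = {chrom: "".join(seq)}
    target_bed = pd.DataFrame(bed_rows)

    samples = [f"s{i + 1:02d}" for i in range(n_samples)]

    def snp_at(pos1: int) -> Variant:
        ref = reference[chrom][pos1 - 1]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        return Variant(chrom, pos1, ref, alt)

    def run_deletion(k: int) -> Variant:
        r = target_start[k] + RUN_OFFSET  # 0-based run start
        anchor = reference[chrom][r - 1]
        return Variant(chrom, r, anchor + "A", anchor)

    def run_insertion(k: int) -> Variant:
        r = target_start[k] + RUN_OFFSET
        anchor = reference[chrom][r - 1]
        return Variant(chrom, r, anchor, anchor + "A")

    variants: list[tuple[Variant, int, np.ndarray]] = []  # (variant, target, genotype col)

    def carrier_column(count: int, hom_all: bool = False) -> np.ndarray:
        col = np.zeros(n_samples, dtype=np.int8)
        idx = rng.choice(n_samples, size=count, replace=False)
        col[idx] = np.where(rng.random(count) < 0.25, 2, 1)
        if hom_all:
            col[:] = 0
            col[idx] = 2
        return col

    base_variants = []
    for k, count in enumerate(polymorphic_carrier_counts):
        if k == 0:
            v = run_deletion(k)
        elif k == 1:
            v = run_insertion(k)
        elif k == 2:
            v = run_deletion(k)
        else:
            v = snp_at(target_start[k] + 101)
        col = carrier_column(count)
        variants.append((v, k, col))
        base_variants.append((v, k, col))
    # same-target duplicates of the first two base variants
    for k in (0, 1):
        dup = snp_at(target_start[k] + 251)
        variants.append((dup, k, base_variants[k][2].copy()))
    # out-of-band variants
    variants.append((snp_at(target_start[10] + 101), 10, carrier_column(n_samples, hom_all=True)))
    variants.append((snp_at(target_start[11] + 101), 11, carrier_column(min(5, n_samples))))
    variants.append((snp_at(target_start[12] + 101), 12, carrier_column(min(20, n_samples))))
    variants.append((snp_at(target_start[13] + 101), 13, carrier_column(1)))

    variants.sort(key=lambda t: (t[0].chrom, t[0].pos))
    keys = [variant_key(v) for v, _, _ in variants]
    genotypes = pd.DataFrame(
        np.stack([c for _, _, c in variants], axis=1), index=samples, columns=keys
    )
    truth_variants = pd.DataFrame(
        [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "key": variant_key(v), "target_id": f"target_{k:02d}"}
            for v, k, _ in variants
        ]
    )

    # survival: effects on the first two base variants, both endpoints
    effect_keys = [variant_key(base_variants[0][0]), variant_key(base_variants[1][0])]
    other_keys = [k for k in keys if k not in effect_keys]
    carriers = genotypes[effect_keys + other_keys]
    surv_frames = []
    covs = pd.DataFrame(
        {
            "sample": samples,
            "sex": ["M"] * 18 + ["F"] * 11 if n_samples == 29
            else list(rng.choice(["M", "F"], n_samples)),
            "neutered": list(rng.permutation(["yes", "no"] * ((n_samples + 1) // 2))[:n_samples]),
            "who_stage": list(rng.choice(["III", "IV", "V"], n_samples, p=[0.1, 0.55, 0.35])),
            "protocol": list(rng.choice(["CHOP", "CHOP_LASP"], n_samples, p=[0.2, 0.8])),
            "age_years": list(rng.integers(2, 12, n_samples)),
        }
    ).set_index("sample")
    for endpoint, scale in (("OS", 1 / 500), ("PFS", 1 / 250)):
        cfg = SimulationConfig(
            seed=seed + (1 if endpoint == "OS" else 2),
            beta=list(planted_beta),
            censor_fraction=censor_fraction,
            baseline_hazard=scale,
        )
        s = simulate_survival(
            carriers, cfg, np.random.default_rng(cfg.seed), endpoint=endpoint
        )
        surv_frames.append(s.join(covs))
    survival = pd.concat(surv_frames)

    truth = {
        "polymorphic_keys": [variant_key(v) for v, _, _ in base_variants]
        + [keys[i] for i, (v, k, _) in enumerate(variants)
           if variant_key(v) not in [variant_key(b[0]) for b in base_variants]
           and k in (0, 1)],
        "duplicate_pairs": [
            [variant_key(base_variants[k][0]),
             variant_key(snp_at(target_start[k] + 251))]
            for k in (0, 1)
        ],
        "effect_variants": dict(zip(effect_keys, planted_beta)),
        "carrier_counts": {variant_key(v): int((c > 0).sum()) for v, _, c in variants},
    }
    return CohortFixture(
        reference, target_bed, truth_variants, genotypes, survival, truth
    )
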