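"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes
rather than any particular sequencing technology: genome pairs related
by recorded edits (with the exact chain file describing the
derivation), LD-block-structured genotype panels built from founder
haplotypes, three discordant variant callers with quality jitter and
non-normalized indel representations, and proportional-hazards survival
times with planted carrier effects. Every generator is deterministic
given (seed, config) and writes a machine-readable ``truth.json``
alongside its standard-format outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import Chain, format_chains
from .config import SimulationConfig
from .consensus import Variant, variant_key
from .core import GenomicInterval
from .haplotype_blocks import GenotypePanel, HaplotypeBlock
from .liftover import revcomp

BASES = np.array(list("ACGT"))

REGION_LEN = 300  # per-SNP source region; the SNP sits at offset 150
SNP_OFFSET = 150
SPACER_LEN = 20
TOO_LONG_INSERT = 901  # pushes a 100-bp window past the 1,000-bp limit


# ---------------------------------------------------------------------------
# small output helpers


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(out_dir, truth: dict) -> None:
    with open(os.path.join(str(out_dir), "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


# ---------------------------------------------------------------------------
# genome pair + chain


@dataclass
class GenomePair:
    source: dict[str, str]
    target: dict[str, str]
    chains: list[Chain]
    snps: pd.DataFrame  # rsid chrom pos ref alt source species p
    truth: dict  # per-rsid intended liftover outcome

    def write(self, out_dir) -> None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(os.path.join(out_dir, "source.fa"), self.source)
        write_fasta(os.path.join(out_dir, "target.fa"), self.target)
        with open(os.path.join(out_dir, "map.chain"), "w") as fh:
            fh.write(format_chains(self.chains))
        self.snps.to_csv(os.path.join(out_dir, "snps.tsv"), sep="\t", index=False)
        write_truth(out_dir, self.truth)


def _region_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    classes = (
        ["no_ortholog"] * config.n_no_ortholog
        + ["too_long"] * config.n_too_long
        + ["unplaced"] * config.n_unplaced
        + ["gap_at_snp"] * config.n_gap_at_snp
        + ["inverted"] * config.n_inverted
    )
    classes += ["conserved"] * (config.n_snps - len(classes))
    rng.shuffle(classes)
    return classes


def simulate_genome_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomePair:
    """Source/target genome pair whose chain exactly records the edits.

    Each SNP owns a 300-bp source region (SNP at offset 150). The
    planted class decides the region's fate in the target genome:
    copied (possibly with substitutions), dropped entirely, stretched by
    an insertion inside the SNP window, moved to an unassembled contig,
    inverted, or copied with the SNP base deleted. With no planted
    edits at all the chain degenerates to a single identity block.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    classes = _region_classes(config, rng)

    src_parts: list[str] = []
    tgt_parts: list[str] = []
    chains: list[Chain] = []
    # regions recorded as (class, src_start, tgt_start_or_None, region seqs)
    records: list[dict] = []
    src_pos = 0
    tgt_pos = 0
    unplaced_contigs: dict[str, str] = {}

    for i, cls in enumerate(classes):
        spacer = _random_seq(rng, SPACER_LEN)
        src_parts.append(spacer)
        tgt_parts.append(spacer)
        src_pos += SPACER_LEN
        tgt_pos += SPACER_LEN

        region = list(_random_seq(rng, REGION_LEN))
        # keep the SNP base distinct from its neighbours so that a
        # deletion at the SNP column has a unique optimal alignment
        tri = rng.permutation(BASES)[:3]
        region[SNP_OFFSET - 1], region[SNP_OFFSET], region[SNP_OFFSET + 1] = tri
        region = "".join(region)
        rec = {
            "class": cls,
            "src_start": src_pos,
            "tgt_start": None,
            "tgt_chrom": None,
        }

        if cls == "no_ortholog":
            tgt_region = ""
        elif cls == "too_long":
            insert = _random_seq(rng, TOO_LONG_INSERT)
            tgt_region = region[:SNP_OFFSET] + insert + region[SNP_OFFSET:]
        elif cls == "unplaced":
            tgt_region = ""  # lives on its own contig instead
            contig = f"chrUn_{i:04d}"
            unplaced_contigs[contig] = region
            rec["tgt_chrom"] = contig
        elif cls == "gap_at_snp":
            tgt_region = region[:SNP_OFFSET] + region[SNP_OFFSET + 1 :]
        elif cls == "inverted":
            tgt_region = revcomp(region)
        else:  # conserved
            tgt_region = list(region)
            if config.substitution_rate > 0:
                for j in range(REGION_LEN):
                    if abs(j - SNP_OFFSET) <= 1:
                        continue  # never touch the SNP column context
                    if rng.random() < config.substitution_rate:
                        tgt_region[j] = rng.choice(
                            [b for b in "ACGT" if b != tgt_region[j]]
                        )
            tgt_region = "".join(tgt_region)

        if tgt_region:
            rec["tgt_start"] = tgt_pos
            rec["tgt_chrom"] = "chr1"
        rec["src_seq"] = region
        records.append(rec)
        src_parts.append(region)
        src_pos += REGION_LEN
        tgt_parts.append(tgt_region)
        tgt_pos += len(tgt_region)

    source = {"chr1": "".join(src_parts)}
    target = {"chr1": "".join(tgt_parts)}
    for contig, seq in sorted(unplaced_contigs.items()):
        target[contig] = seq
    src_len = len(source["chr1"])
    tgt_len = len(target["chr1"])

    planted = any(r["class"] != "conserved" for r in records)
    if not planted and config.substitution_rate == 0 and records:
        # identity case: one whole-chromosome chain with a single block
        chains.append(
            Chain(src_len, "chr1", src_len, 0, src_len,
                  "chr1", tgt_len, "+", 0, tgt_len, 1, blocks=[(src_len, 0, 0)])
        )
    else:
        cid = 0
        for rec in records:
            cls = rec["class"]
            if cls == "no_ortholog":
                continue
            cid += 1
            s0 = rec["src_start"]
            if cls == "too_long":
                t0 = rec["tgt_start"]
                chains.append(
                    Chain(REGION_LEN, "chr1", src_len, s0, s0 + REGION_LEN,
                          "chr1", tgt_len, "+", t0, t0 + REGION_LEN + TOO_LONG_INSERT,
                          cid,
                          blocks=[(SNP_OFFSET, 0, TOO_LONG_INSERT),
                                  (REGION_LEN - SNP_OFFSET, 0, 0)])
                )
            elif cls == "unplaced":
                contig = rec["tgt_chrom"]
                chains.append(
                    Chain(REGION_LEN, "chr1", src_len, s0, s0 + REGION_LEN,
                          contig, REGION_LEN, "+", 0, REGION_LEN, cid,
                          blocks=[(REGION_LEN, 0, 0)])
                )
            elif cls == "gap_at_snp":
                t0 = rec["tgt_start"]
                chains.append(
                    Chain(REGION_LEN - 1, "chr1", src_len, s0, s0 + REGION_LEN,
                          "chr1", tgt_len, "+", t0, t0 + REGION_LEN - 1, cid,
                          blocks=[(SNP_OFFSET, 1, 0),
                                  (REGION_LEN - SNP_OFFSET - 1, 0, 0)])
                )
            elif cls == "inverted":
                t0 = rec["tgt_start"]
                # q coordinates on the reverse-complemented target strand
                q_start = tgt_len - (t0 + REGION_LEN)
                chains.append(
                    Chain(REGION_LEN, "chr1", src_len, s0, s0 + REGION_LEN,
                          "chr1", tgt_len, "-", q_start, q_start + REGION_LEN, cid,
                          blocks=[(REGION_LEN, 0, 0)])
                )
            else:
                t0 = rec["tgt_start"]
                chains.append(
                    Chain(REGION_LEN, "chr1", src_len, s0, s0 + REGION_LEN,
                          "chr1", tgt_len, "+", t0, t0 + REGION_LEN, cid,
                          blocks=[(REGION_LEN, 0, 0)])
                )

    rows = []
    truth: dict[str, dict] = {}
    for i, rec in enumerate(records):
        rsid = f"rs{100001 + i}"
        pos1 = rec["src_start"] + SNP_OFFSET + 1  # 1-based
        ref = rec["src_seq"][SNP_OFFSET]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        rows.append(
            {"rsid": rsid, "chrom": "chr1", "pos": pos1, "ref": ref, "alt": alt,
             "source": "synthetic", "species": "human", "p": ""}
        )
        expected = "conserved" if rec["class"] == "inverted" else rec["class"]
        truth[rsid] = {
            "class": rec["class"],
            "expected_status": expected,
            "source_pos": pos1,
            "target_chrom": rec["tgt_chrom"] or "",
        }
    snps = pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "ref", "alt", "source", "species", "p"]
    )
    return GenomePair(source, target, chains, snps, truth)


# ---------------------------------------------------------------------------
# accounting fixture (filter-cascade composition)


@dataclass
class AccountingComposition:
    """Counts per liftover outcome class, plus target-species literature SNPs."""

    n_input: int = 592
    n_no_ortholog: int = 68
    n_too_long: int = 1
    n_unplaced: int = 1
    n_gap_at_snp: int = 43
    n_literature: int = 3

    @property
    def n_conserved(self) -> int:
        return (
            self.n_input - self.n_no_ortholog - self.n_too_long
            - self.n_unplaced - self.n_gap_at_snp
        )

    def validate(self) -> None:
        if min(self.n_input, self.n_no_ortholog, self.n_too_long,
               self.n_unplaced, self.n_gap_at_snp, self.n_literature) < 0:
            raise ValueError("composition counts must be non-negative")
        if self.n_conserved < 0:
            raise ValueError("outcome class counts exceed the input count")


@dataclass
class AccountingFixture:
    pair: GenomePair
    literature_snps: pd.DataFrame  # rsid chrom pos (target genome, 1-based)
    composition: AccountingComposition


def make_accounting_fixture(
    composition: AccountingComposition | None = None, seed: int = 0
) -> AccountingFixture:
    """Bundle whose filter cascade provably yields the composed class sizes."""
    composition = composition or AccountingComposition()
    composition.validate()
    cfg = SimulationConfig(
        seed=seed,
        n_snps=composition.n_input,
        n_no_ortholog=composition.n_no_ortholog,
        n_too_long=composition.n_too_long,
        n_unplaced=composition.n_unplaced,
        n_gap_at_snp=composition.n_gap_at_snp,
    )
    rng = np.random.default_rng(seed)
    pair = simulate_genome_pair(cfg, rng)
    # target-species literature SNPs: genuine target-chromosome coordinates,
    # placed in inter-region spacers so they collide with no lifted locus
    lit_rows = []
    tgt_len = len(pair.target.get("chr1", ""))
    for k in range(composition.n_literature):
        pos = 5 + k * max(1, (tgt_len - 10) // max(1, composition.n_literature))
        lit_rows.append({"rsid": f"litSNP{k + 1}", "chrom": "chr1", "pos": pos + 1})
    literature = pd.DataFrame(lit_rows, columns=["rsid", "chrom", "pos"])
    return AccountingFixture(pair, literature, composition)


# ---------------------------------------------------------------------------
# LD-structured genotype panel


@dataclass
class LdTruth:
    blocks: list[HaplotypeBlock]
    founder_freqs: list[float]
    haplotypes: np.ndarray  # (2*n_subjects, n_markers) phased alleles


def simulate_genotypes_ld(
    config: SimulationConfig, rng: np.random.Generator | None = None,
    chrom: str = "chr1",
) -> tuple[GenotypePanel, LdTruth]:
    """Founder-haplotype panel with planted blocks and free recombination.

    Within a block every chromosome copies one of ``founder_haplotypes``
    founder haplotypes, generated on a perfect phylogeny so that
    within-block |D'| = 1 absent mutation; between blocks the founder
    lineage switches with the block's ``recomb_rate_between``.
    Genotypes are emitted unphased; the phased haplotypes and the true
    block coordinates go into the truth set.
    """
    config.validate()
    if not config.block_spec:
        raise ValueError("block_spec must be non-empty")
    rng = rng or np.random.default_rng(config.seed)
    n_hap = 2 * config.n_subjects
    nf = config.founder_haplotypes

    positions: list[int] = []
    blocks: list[HaplotypeBlock] = []
    founder_freqs: list[float] = []
    hap_cols: list[np.ndarray] = []
    pos = 1000
    prev_lineage = None
    for spec in config.block_spec:
        m = spec.n_markers
        start_idx = len(positions)
        block_pos = [pos + round(j * (spec.span_bp - 1) / (m - 1)) for j in range(m)]
        positions.extend(block_pos)
        pos = block_pos[-1] + config.inter_block_gap_bp

        # founder haplotypes on a perfect phylogeny: every marker mutates
        # exactly once on the founder tree, so any two markers show at
        # most three of the four gametes and within-block |D'| = 1
        founders = np.zeros((nf, m), dtype=np.int8)
        chunks = np.array_split(rng.permutation(m), nf - 1)
        for f in range(1, nf):
            parent = int(rng.integers(0, f))
            founders[f] = founders[parent]
            founders[f, chunks[f - 1]] ^= 1
        p0 = float(rng.uniform(0.2, 0.8))
        founder_freqs.append(p0)
        if nf == 2:
            probs = np.array([p0, 1 - p0])
        else:
            probs = rng.dirichlet(np.full(nf, 5.0))

        drawn = rng.choice(nf, size=n_hap, p=probs)
        if prev_lineage is None:
            lineage = drawn
        else:
            recomb = rng.random(n_hap) < spec.recomb_rate_between
            lineage = np.where(recomb, drawn, prev_lineage % nf)
        prev_lineage = lineage
        block = founders[lineage]
        if config.mutation_rate > 0:
            flips = rng.random(block.shape) < config.mutation_rate
            block = block ^ flips.astype(np.int8)
        hap_cols.append(block)
        blocks.append(
            HaplotypeBlock(chrom, start_idx, start_idx + m - 1,
                           block_pos[-1] - block_pos[0] + 1)
        )

    haplotypes = np.concatenate(hap_cols, axis=1)
    genotypes = haplotypes[0::2] + haplotypes[1::2]
    ids = [f"snp{i + 1:05d}" for i in range(len(positions))]
    samples = [f"s{i + 1:03d}" for i in range(config.n_subjects)]
    panel = GenotypePanel(
        [chrom] * len(positions), np.array(positions), ids,
        genotypes.astype(np.int8), samples,
    )
    return panel, LdTruth(blocks, founder_freqs, haplotypes)


def write_pedmap(panel: GenotypePanel, prefix) -> None:
    """PLINK text PED/MAP; alleles A (reference) / G (alternate)."""
    with open(f"{prefix}.map", "w") as fh:
        for c, i, p in zip(panel.chroms, panel.ids, panel.positions):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    code = {0: "A A", 1: "A G", 2: "G G", -1: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for s, row in zip(panel.samples, panel.genotypes):
            alleles = " ".join(code[int(g)] for g in row)
            fh.write(f"FAM {s} 0 0 0 -9 {alleles}\n")


def write_genotype_vcf(panel: GenotypePanel, path, contig_len: int | None = None) -> None:
    contigs: dict[str, int] = {}
    for c, p in zip(panel.chroms, panel.positions):
        contigs[c] = max(contigs.get(c, 0), int(p) + 1000)
    if contig_len:
        contigs = {c: contig_len for c in contigs}
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contigs.items()]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples))
    for j, (c, p, i) in enumerate(zip(panel.chroms, panel.positions, panel.ids)):
        gts = "\t".join(gt[int(g)] for g in panel.genotypes[:, j])
        lines.append(f"{c}\t{p}\t{i}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# caller-discordance VCF emulation


def _homopolymer_run(seq: str, start0: int) -> int:
    """Length of the run of identical bases starting at ``start0``."""
    b = seq[start0]
    k = start0
    while k < len(seq) and seq[k] == b:
        k += 1
    return k - start0


def denormalize_variant(genome: dict[str, str], v: Variant) -> Variant:
    """A right-shifted and/or padded representation of an indel.

    Inverse of normalization: the returned variant denotes the same
    edit but is not parsimonious/left-aligned. SNPs and complex alleles
    are returned unchanged.
    """
    seq = genome[v.chrom]
    if len(v.ref) == 2 and len(v.alt) == 1 and v.ref[0] == v.alt:
        b = v.ref[1]
        run = _homopolymer_run(seq, v.pos)  # run of the deleted base
        if run >= 2:
            # delete the run's last base instead: non-parsimonious 2-base form
            return Variant(v.chrom, v.pos + run - 1, b + b, b)
        nxt = seq[v.pos + 1] if v.pos + 1 < len(seq) else None
        if nxt:
            return Variant(v.chrom, v.pos, v.ref + nxt, v.alt + nxt)
    elif len(v.ref) == 1 and len(v.alt) == 2 and v.alt[0] == v.ref:
        b = v.alt[1]
        run = _homopolymer_run(seq, v.pos) if v.pos < len(seq) and seq[v.pos] == b else 0
        if run >= 1:
            return Variant(v.chrom, v.pos + run, b, b + b)
        nxt = seq[v.pos] if v.pos < len(seq) else None
        if nxt:
            return Variant(v.chrom, v.pos, v.ref + nxt, v.alt + nxt)
    return v


def simulate_caller_vcfs(
    reference: dict[str, str],
    truth_variants: pd.DataFrame,  # chrom pos ref alt (normalized)
    genotypes: pd.DataFrame,  # samples x variant_key, codes 0/1/2
    config: SimulationConfig,
    out_dir,
    callers: tuple[str, ...] = ("caller1", "caller2", "caller3"),
    rng: np.random.Generator | None = None,
) -> dict:
    """Three imperfect callers per sample: truth minus FN plus FP.

    Each caller drops true calls at ``caller_fn_rate``, adds spurious
    SNP calls at ``caller_fp_rate`` (per true site), assigns a QUAL
    below 20 at ``caller_lowqual_rate``, and emits indels in a
    right-shifted non-parsimonious representation at
    ``indel_jitter_rate``. Returns the per-file truth labels.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    variants = [
        Variant(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in truth_variants.itertuples(index=False)
    ]
    truth_positions = {(v.chrom, v.pos) for v in variants}
    labels: dict[str, dict] = {}
    contig_header = [
        f"##contig=<ID={c},length={len(s)}>" for c, s in reference.items()
    ]
    for sample in genotypes.index:
        for caller in callers:
            records = []
            file_labels = {"fn": [], "fp": [], "jittered": [], "low_qual": []}
            for v in variants:
                g = int(genotypes.loc[sample, variant_key(v)])
                if g <= 0:
                    continue
                if rng.random() < config.caller_fn_rate:
                    file_labels["fn"].append(variant_key(v))
                    continue
                emit = v
                if len(v.ref) != len(v.alt) and rng.random() < config.indel_jitter_rate:
                    emit = denormalize_variant(reference, v)
                    if emit != v:
                        file_labels["jittered"].append(variant_key(v))
                if rng.random() < config.caller_lowqual_rate:
                    qual = round(float(rng.uniform(5, 19.5)), 1)
                    file_labels["low_qual"].append(variant_key(v))
                else:
                    qual = round(float(rng.uniform(20.5, 60)), 1)
                records.append((emit, qual, g))
            n_fp = rng.binomial(len(variants), config.caller_fp_rate)
            placed = 0
            while placed < n_fp:
                chrom = sorted(reference)[rng.integers(0, len(reference))]
                pos = int(rng.integers(2, len(reference[chrom])))
                if (chrom, pos) in truth_positions:
                    continue
                ref = reference[chrom][pos - 1]
                if ref not in "ACGT":
                    continue
                alt = rng.choice([b for b in "ACGT" if b != ref])
                fp = Variant(chrom, pos, ref, str(alt))
                records.append((fp, round(float(rng.uniform(20.5, 60)), 1), 1))
                file_labels["fp"].append(variant_key(fp))
                placed += 1
            records.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].ref, r[0].alt))
            path = os.path.join(out_dir, f"{sample}.{caller}.vcf")
            gt = {1: "0/1", 2: "1/1"}
            with open(path, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                fh.write("\n".join(contig_header) + "\n")
                fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
                fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
                for v, qual, g in records:
                    fh.write(
                        f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t.\tGT\t{gt[g]}\n"
                    )
            labels[f"{sample}.{caller}"] = file_labels
    return labels


# ---------------------------------------------------------------------------
# proportional-hazards survival times


def simulate_survival(
    carriers: pd.DataFrame,  # samples x variants, 0/1 carrier codes (or 0/1/2)
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Event times from a Weibull/exponential PH model with planted betas.

    ``config.beta`` applies to the first ``len(beta)`` variant columns
    (remaining variants have no effect). Censoring is independent
    exponential, with its rate calibrated by bisection so the expected
    censored fraction matches ``config.censor_fraction``.
    """
    config.validate()
    if len(config.beta) > carriers.shape[1]:
        raise ValueError("more beta coefficients than variants")
    rng = rng or np.random.default_rng(config.seed)
    X = (carriers.to_numpy(dtype=float) > 0).astype(float)
    beta = np.zeros(X.shape[1])
    beta[: len(config.beta)] = config.beta
    eta = X @ beta
    u = rng.uniform(size=len(X))
    base = -np.log(u) / (config.baseline_hazard * np.exp(eta))
    t_event = base ** (1.0 / config.weibull_shape)

    frac = config.censor_fraction
    if frac <= 0:
        time, event = t_event, np.ones(len(X), dtype=int)
    else:
        lo, hi = 1e-12, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if np.mean(1 - np.exp(-mid * t_event)) < frac:
                lo = mid
            else:
                hi = mid
        lam_c = np.sqrt(lo * hi)
        t_cens = rng.exponential(1 / lam_c, size=len(X))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)
    return pd.DataFrame(
        {
            "sample": list(carriers.index),
            "time": time,
            "event": event,
            "endpoint": endpoint,
        }
    ).set_index("sample")
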