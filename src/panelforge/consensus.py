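"""Three-caller consensus genotyping and cohort-level variant filters.

Per sample, each caller's calls are quality-filtered (QUAL >= 20),
left-align/parsimony normalized, and matched on chrom+pos+ref+alt
(SNPs and indels alike). A variant is a per-sample consensus call when
all three callers report it; the "pooled" set is every variant that is
a consensus call in at least one sample. Cohort filters then keep
variants carried by an intermediate number of subjects and collapse
same-target variants with identical genotype patterns.
"""

from __future__ import annotations

import os
from collections import namedtuple
from dataclasses import dataclass

import pandas as pd

from .liftover import fetch

Variant = namedtuple("Variant", ["chrom", "pos", "ref", "alt"])  # pos is 1-based

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
DEFAULT_CALLERS = ("caller1", "caller2", "caller3")


@dataclass(frozen=True)
class CallerCall:
    sample_id: str
    caller_id: str
    variant: Variant
    qual: float
    genotype: int  # 0/1/2

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError("negative QUAL")
        if self.variant.ref == self.variant.alt:
            raise ValueError("ref and alt alleles are identical")


# ---------------------------------------------------------------------------
# normalization (left-align + parsimony)


def normalize_variant(genome, variant: Variant) -> Variant:
    """Left-aligned, parsimonious representation of a variant.

    Standard normalization: trim a shared trailing base while both
    alleles keep one; if either allele empties, extend both to the left
    with the preceding reference base; finally trim shared leading
    bases. Idempotent; raises when REF does not match the genome.
    """
    chrom, pos, ref, alt = variant
    observed = fetch(genome, chrom, pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref.upper():
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: variant says {ref!r}, genome has {observed!r}"
        )
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
        if len(ref) == 0 or len(alt) == 0:
            if pos == 1:
                raise ValueError(f"cannot left-extend at {chrom}:1")
            pos -= 1
            base = fetch(genome, chrom, pos - 1, pos).upper()
            ref, alt = base + ref, base + alt
            continue
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(chrom, pos, ref, alt)


def variant_class(v: Variant) -> str:
    return "snp" if len(v.ref) == 1 and len(v.alt) == 1 else "indel"


# ---------------------------------------------------------------------------
# VCF input


def read_caller_vcf(path, sample_id: str, caller_id: str) -> list[CallerCall]:
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gt = None
            if rec.samples:
                gt = rec.samples[0].get("GT")
            if gt is None or any(a is None for a in gt):
                code = HET
            else:
                n_alt = sum(1 for a in gt if a != 0)
                code = HOM_ALT if n_alt == 2 else (HET if n_alt == 1 else HOM_REF)
            calls.append(
                CallerCall(
                    sample_id,
                    caller_id,
                    Variant(rec.chrom, rec.pos, rec.ref, rec.alts[0]),
                    float(rec.qual if rec.qual is not None else 0.0),
                    code,
                )
            )
    return calls


def load_cohort_calls(
    vcf_dir,
    samples: list[str],
    callers: tuple[str, ...] = DEFAULT_CALLERS,
    pattern: str = "{sample}.{caller}.vcf",
) -> dict[str, dict[str, list[CallerCall]]]:
    """Calls indexed by sample then caller; missing files are an error."""
    out: dict[str, dict[str, list[CallerCall]]] = {}
    missing = []
    for s in samples:
        out[s] = {}
        for c in callers:
            path = os.path.join(str(vcf_dir), pattern.format(sample=s, caller=c))
            if not os.path.exists(path):
                missing.append(f"{s}/{c}")
                continue
            out[s][c] = read_caller_vcf(path, s, c)
    if missing:
        raise FileNotFoundError(f"missing caller VCFs for: {', '.join(missing)}")
    return out


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusResult:
    pooled: list[Variant]  # normalized, sorted
    matrix: pd.DataFrame  # samples x variant-key, codes 0/1/2/-1
    per_sample_consensus: dict[str, dict[Variant, int]]


def variant_key(v: Variant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


def _consensus_genotype(codes: list[int]) -> int:
    """All agree -> that code; 2-vs-1 -> majority; three-way split -> het."""
    uniq = set(codes)
    if len(uniq) == 1:
        return codes[0]
    for c in uniq:
        if codes.count(c) == 2:
            return c
    return HET


def consensus(
    cohort_calls: dict[str, dict[str, list[CallerCall]]],
    genome,
    min_qual: float = 20.0,
    carrier_rule: str = "strict",
) -> ConsensusResult:
    """Pooled-variant set and per-sample genotype matrix.

    ``carrier_rule`` decides the genotype of a pooled variant in a
    sample where only one or two callers report it: "strict" marks it
    missing; "any_caller" treats any call as evidence of a carrier and
    uses the callers' (majority) genotype. Samples with no call at all
    are homozygous reference.
    """
    if carrier_rule not in ("strict", "any_caller"):
        raise ValueError(f"unknown carrier_rule {carrier_rule!r}")
    per_sample: dict[str, dict[Variant, list[int]]] = {}
    per_sample_consensus: dict[str, dict[Variant, int]] = {}
    pooled: set[Variant] = set()
    for sample, by_caller in sorted(cohort_calls.items()):
        n_callers = len(by_caller)
        seen: dict[Variant, dict[str, int]] = {}
        for caller, calls in by_caller.items():
            for call in calls:
                if call.qual < min_qual:
                    continue
                v = normalize_variant(genome, call.variant)
                # keep the first record per caller for a duplicated site
                seen.setdefault(v, {}).setdefault(caller, call.genotype)
        cons: dict[Variant, int] = {}
        partial: dict[Variant, list[int]] = {}
        for v, by in seen.items():
            if len(by) == n_callers:
                cons[v] = _consensus_genotype(list(by.values()))
                pooled.add(v)
            else:
                partial[v] = list(by.values())
        per_sample_consensus[sample] = cons
        per_sample[sample] = partial

    pooled_sorted = sorted(pooled)
    samples = sorted(cohort_calls)
    rows = []
    for sample in samples:
        cons = per_sample_consensus[sample]
        partial = per_sample[sample]
        row = []
        for v in pooled_sorted:
            if v in cons:
                row.append(cons[v])
            elif v in partial:
                if carrier_rule == "strict":
                    row.append(MISSING)
                else:
                    row.append(_majority(partial[v]))
            else:
                row.append(HOM_REF)
        rows.append(row)
    matrix = pd.DataFrame(
        rows, index=samples, columns=[variant_key(v) for v in pooled_sorted]
    )
    return ConsensusResult(pooled_sorted, matrix, per_sample_consensus)


def _majority(codes: list[int]) -> int:
    uniq = sorted(set(codes))
    if len(uniq) == 1:
        return codes[0]
    counts = [(codes.count(c), c) for c in uniq]
    counts.sort(reverse=True)
    if counts[0][0] > counts[1][0]:
        return counts[0][1]
    return HET


# ---------------------------------------------------------------------------
# cohort filters


def cohort_filter(
    matrix: pd.DataFrame, min_carriers: int = 11, max_carriers: int = 18
) -> list[str]:
    """Variants carried by 11-18 subjects with everyone else hom-ref.

    Carriers are subjects with genotype > 0; a missing genotype in any
    remaining subject disqualifies the variant.
    """
    keep = []
    for col in matrix.columns:
        g = matrix[col]
        carriers = int((g > 0).sum())
        if min_carriers <= carriers <= max_carriers and int((g == HOM_REF).sum()) == len(g) - carriers:
            keep.append(col)
    return keep


def dedup_patterns(
    variant_keys: list[str],
    matrix: pd.DataFrame,
    target_of: dict[str, str],
) -> tuple[list[str], dict[str, str]]:
    """Collapse same-target variants with identical genotype vectors.

    Within each (target, genotype-pattern) group the variant with the
    smallest coordinate is kept; the returned mapping records each
    removed variant's kept representative. Idempotent.
    """
    def coord(key: str) -> tuple[str, int, str, str]:
        chrom, pos, ref, alt = key.split(":")
        return (chrom, int(pos), ref, alt)

    groups: dict[tuple[str, tuple], list[str]] = {}
    for k in variant_keys:
        sig = (target_of.get(k, ""), tuple(matrix[k].tolist()))
        groups.setdefault(sig, []).append(k)
    kept, removed = [], {}
    for members in groups.values():
        members.sort(key=coord)
        kept.append(members[0])
        for dup in members[1:]:
            removed[dup] = members[0]
    kept.sort(key=coord)
    return kept, removed


def assign_targets(
    variants: list[Variant], target_bed: pd.DataFrame
) -> dict[str, str]:
    """Map each variant to the target window containing it (if any)."""
    out = {}
    for v in variants:
        hit = ""
        for row in target_bed.itertuples(index=False):
            if row.chrom == v.chrom and row.start < v.pos <= row.end:
                hit = row.name
                break
        out[variant_key(v)] = hit
    return out


def write_pooled_vcf(path, result: ConsensusResult, contigs: dict[str, int]) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = list(result.matrix.index)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    for v in result.pooled:
        codes = result.matrix[variant_key(v)]
        gts = "\t".join(gt_str[int(codes[s])] for s in samples)
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
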