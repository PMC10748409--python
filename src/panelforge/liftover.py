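"""SNP-window liftover and cross-species conservation classification.

For each source-species SNP a 100-bp window centered on the SNP is
lifted to the target genome through a chain file. Windows with no
ortholog, an over-long ortholog (default > 1,000 bp), or a placement on
an unassembled contig are excluded; the surviving windows are aligned
source-vs-target and the SNP is conserved only if its alignment column
is not a gap in the target row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .alignment import AlignScoring, align_pair
from .chain import ChainIndex, LiftFailure, lift_interval
from .core import GenomicInterval, SnpRecord

STATUSES = ("conserved", "no_ortholog", "too_long", "unplaced", "gap_at_snp")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract a subsequence from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end]
    return str(seq[start:end])


def chrom_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


@dataclass
class WindowedSnp:
    snp: SnpRecord
    window: GenomicInterval
    snp_offset: int  # 0-based offset of the SNP base within the window
    truncated: bool = False


@dataclass
class OrthologResult:
    snp: SnpRecord
    status: str
    target_locus: GenomicInterval | None = None
    target_snp_offset: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def window_around(snp: SnpRecord, chrom_len: int, flank: int = 50) -> WindowedSnp:
    """Window of ``2*flank`` bases centered on the SNP.

    The SNP base sits at 0-based offset ``flank`` (``flank`` bases to its
    left, ``flank - 1`` to its right). Windows running off a chromosome
    end are truncated and flagged.
    """
    if snp.pos < 1:
        raise ValueError(f"{snp.rsid}: SNP has no coordinate")
    pos0 = snp.pos - 1
    start = pos0 - flank
    end = pos0 + flank
    truncated = False
    if start < 0:
        warnings.warn(f"{snp.rsid}: window truncated at chromosome start")
        start, truncated = 0, True
    if end > chrom_len:
        warnings.warn(f"{snp.rsid}: window truncated at chromosome end")
        end, truncated = chrom_len, True
    return WindowedSnp(snp, GenomicInterval(snp.chrom, start, end), pos0 - start, truncated)


def classify_snp(
    window_seq_source: str,
    lifted_seq_target: str,
    snp_offset: int,
    target_locus: GenomicInterval,
    max_target_len: int = 1000,
    unplaced_prefix: str = "chrUn",
    scoring: AlignScoring = AlignScoring(),
) -> str:
    """Conservation status of one lifted SNP window.

    Precedence: too_long, unplaced, gap_at_snp, conserved (an unmapped
    window never reaches this function; it is no_ortholog upstream).
    """
    if not (0 <= snp_offset < len(window_seq_source)):
        raise ValueError(f"snp_offset {snp_offset} outside window")
    if len(target_locus) > max_target_len:
        return "too_long"
    if target_locus.chrom.startswith(unplaced_prefix):
        return "unplaced"
    aln = align_pair(window_seq_source, lifted_seq_target, scoring)
    if aln.target_has_gap_at_source_offset(snp_offset):
        return "gap_at_snp"
    return "conserved"


def run_cascade(
    snps: list[SnpRecord],
    source_genome,
    target_genome,
    chain_index: ChainIndex,
    flank: int = 50,
    min_mapped_fraction: float = 0.95,
    max_target_len: int = 1000,
    unplaced_prefix: str = "chrUn",
    scoring: AlignScoring = AlignScoring(),
) -> list[OrthologResult]:
    """Apply the full ortholog/conservation filter cascade to a SNP list."""
    results: list[OrthologResult] = []
    for snp in snps:
        ws = window_around(snp, chrom_length(source_genome, snp.chrom), flank)
        lifted = lift_interval(chain_index, ws.window, min_mapped_fraction)
        if isinstance(lifted, LiftFailure):
            results.append(OrthologResult(snp, "no_ortholog", detail=lifted.detail))
            continue
        locus = lifted.interval
        src_seq = fetch(source_genome, ws.window.chrom, ws.window.start, ws.window.end)
        tgt_seq = fetch(target_genome, locus.chrom, locus.start, locus.end)
        if locus.strand == "-":
            tgt_seq = revcomp(tgt_seq)
        status = classify_snp(
            src_seq, tgt_seq, ws.snp_offset, locus,
            max_target_len=max_target_len,
            unplaced_prefix=unplaced_prefix,
            scoring=scoring,
        )
        target_snp_offset = None
        snp_pos0 = snp.pos - 1
        if snp_pos0 in lifted.base_map:
            mapped = lifted.base_map[snp_pos0]
            target_snp_offset = (
                locus.end - 1 - mapped if locus.strand == "-" else mapped - locus.start
            )
        results.append(OrthologResult(snp, status, locus, target_snp_offset))
    return results


def status_counts(results: list[OrthologResult]) -> dict[str, int]:
    counts = {s: 0 for s in STATUSES}
    for r in results:
        counts[r.status] += 1
    return counts


def results_table(results: list[OrthologResult]) -> pd.DataFrame:
    """Per-SNP status table with 1-based target coordinates."""
    rows = []
    for r in results:
        rows.append(
            {
                "rsid": r.snp.rsid,
                "source_chrom": r.snp.chrom,
                "source_pos": r.snp.pos,
                "status": r.status,
                "target_chrom": r.target_locus.chrom if r.target_locus else "",
                "target_start": r.target_locus.start + 1 if r.target_locus else 0,
                "target_end": r.target_locus.end if r.target_locus else 0,
                "target_strand": r.target_locus.strand if r.target_locus else "",
            }
        )
    return pd.DataFrame(rows)


def conserved_bed(results: list[OrthologResult]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.target_locus.chrom,
            "start": r.target_locus.start,
            "end": r.target_locus.end,
            "name": r.snp.rsid,
            "score": 0,
            "strand": r.target_locus.strand,
        }
        for r in results
        if r.status == "conserved"
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
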