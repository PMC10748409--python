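"""Global pairwise DNA alignment used for the conservation call.

The conservation rule only needs a source-vs-destination pairwise
alignment (does the column holding the SNP have a gap in the other
species?), so the aligner is a standard Needleman–Wunsch with linear gap
cost, delegated to Bio.Align.PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_DNA = set("ACGTN")


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped rows; removing '-' recovers the inputs."""

    source_row: str
    target_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.source_row) != len(self.target_row):
            raise ValueError("alignment rows differ in length")

    def column_of_source_offset(self, offset: int) -> int:
        """Alignment column holding the source base at ``offset``."""
        seen = -1
        for col, ch in enumerate(self.source_row):
            if ch != "-":
                seen += 1
                if seen == offset:
                    return col
        raise IndexError(f"source offset {offset} beyond aligned sequence")

    def target_has_gap_at_source_offset(self, offset: int) -> bool:
        return self.target_row[self.column_of_source_offset(offset)] == "-"


def _check_dna(seq: str, label: str) -> None:
    bad = set(seq.upper()) - _DNA
    if bad:
        raise ValueError(f"{label} contains non-DNA symbols: {sorted(bad)}")


def align_pair(
    source_seq: str,
    target_seq: str,
    scoring: AlignScoring = AlignScoring(),
) -> PairwiseAlignment:
    """Optimal global alignment (match/mismatch/linear gap)."""
    source_seq = source_seq.upper()
    target_seq = target_seq.upper()
    _check_dna(source_seq, "source sequence")
    _check_dna(target_seq, "target sequence")
    if not source_seq and not target_seq:
        return PairwiseAlignment("", "", 0.0)
    if not source_seq or not target_seq:
        n = len(source_seq or target_seq)
        return PairwiseAlignment(
            source_seq or "-" * n, target_seq or "-" * n, scoring.gap * n
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    aln = aligner.align(source_seq, target_seq)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))
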