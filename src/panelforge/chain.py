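"""UCSC chain files: parsing, writing, and interval lifting.

A chain describes a gapped alignment between a source ("t", the genome
coordinates are lifted *from*) and a destination ("q", the genome lifted
*to*) as a list of ungapped blocks separated by source-only (dt) and
destination-only (dq) gaps. Destination coordinates of minus-strand
chains are expressed on the reverse-complemented sequence, as in the
UCSC dialect; :meth:`Chain.map_base` converts them back to forward
coordinates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .core import GenomicInterval


class ChainParseError(ValueError):
    """Raised on malformed chain input; carries the offending line number."""


@dataclass
class Chain:
    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    # aligned blocks as (size, dt, dq); dt/dq of the last block are 0
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t_span = sum(s + dt for s, dt, _ in self.blocks)
        q_span = sum(s + dq for s, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks span {t_span} source bases, "
                f"header says {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks span {q_span} destination bases, "
                f"header says {self.q_end - self.q_start}"
            )
        # precompute per-block offsets for binary search
        self._t_starts: list[int] = []
        self._q_starts: list[int] = []
        self._sizes: list[int] = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            self._t_starts.append(t)
            self._q_starts.append(q)
            self._sizes.append(size)
            t += size + dt
            q += size + dq

    def map_base(self, t_pos: int) -> int | None:
        """Map one source position to a forward-strand destination position.

        Returns None when the position falls in a source-side gap or
        outside the chain span.
        """
        if not (self.t_start <= t_pos < self.t_end):
            return None
        i = bisect.bisect_right(self._t_starts, t_pos) - 1
        if i < 0:
            return None
        off = t_pos - self._t_starts[i]
        if off >= self._sizes[i]:
            return None  # inside a dt gap
        q = self._q_starts[i] + off
        if self.q_strand == "-":
            return self.q_size - 1 - q
        return q

    def map_interval_bases(self, start: int, end: int) -> dict[int, int]:
        """Forward-strand destination position for every mappable base."""
        out: dict[int, int] = {}
        i = max(0, bisect.bisect_right(self._t_starts, start) - 1)
        for j in range(i, len(self._sizes)):
            t0, q0, size = self._t_starts[j], self._q_starts[j], self._sizes[j]
            if t0 >= end:
                break
            a, b = max(start, t0), min(end, t0 + size)
            for t in range(a, b):
                q = q0 + (t - t0)
                out[t] = self.q_size - 1 - q if self.q_strand == "-" else q
        return out


@dataclass
class LiftFailure:
    reason: str  # currently always "no_ortholog"
    detail: str = ""


@dataclass
class LiftResult:
    interval: GenomicInterval
    chain: Chain
    mapped_fraction: float
    base_map: dict[int, int]


class ChainIndex:
    """All chains of a file, queryable by source chromosome."""

    def __init__(self, chains: list[Chain]):
        self.chains = list(chains)
        self._by_chrom: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_chrom.setdefault(c.t_name, []).append(c)

    def overlapping(self, interval: GenomicInterval) -> list[Chain]:
        return [
            c
            for c in self._by_chrom.get(interval.chrom, [])
            if c.t_start < interval.end and interval.start < c.t_end
        ]

    @classmethod
    def from_file(cls, path) -> "ChainIndex":
        with open(path) as fh:
            return cls(parse_chains(fh.read()))


def parse_chains(text: str) -> list[Chain]:
    chains: list[Chain] = []
    header = None
    blocks: list[tuple[int, int, int]] = []
    header_line = 0

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ChainParseError(
                f"line {lineno}: chain starting at line {header_line} "
                "does not end with a bare block size"
            )
        try:
            chains.append(Chain(*header, blocks=blocks))
        except ValueError as e:
            raise ChainParseError(f"line {header_line}: {e}") from e
        header, blocks = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "chain":
            finish(lineno)
            if len(fields) != 13:
                raise ChainParseError(f"line {lineno}: chain header needs 13 fields")
            try:
                header = (
                    int(fields[1]), fields[2], int(fields[3]),
                    int(fields[5]), int(fields[6]),
                    fields[7], int(fields[8]), fields[9],
                    int(fields[10]), int(fields[11]), int(fields[12]),
                )
            except ValueError as e:
                raise ChainParseError(f"line {lineno}: {e}") from e
            if fields[4] != "+":
                raise ChainParseError(f"line {lineno}: source strand must be '+'")
            if fields[9] not in ("+", "-"):
                raise ChainParseError(f"line {lineno}: bad destination strand")
            header_line = lineno
        else:
            if header is None:
                raise ChainParseError(f"line {lineno}: block line outside a chain")
            try:
                nums = [int(x) for x in fields]
            except ValueError as e:
                raise ChainParseError(f"line {lineno}: {e}") from e
            if len(nums) == 1:
                blocks.append((nums[0], 0, 0))
            elif len(nums) == 3:
                blocks.append((nums[0], nums[1], nums[2]))
            else:
                raise ChainParseError(f"line {lineno}: block line needs 1 or 3 fields")
    finish(len(text.splitlines()) + 1)
    return chains


def format_chains(chains: list[Chain]) -> str:
    out = []
    for c in chains:
        out.append(
            f"chain {c.score} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
            f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}"
        )
        for k, (size, dt, dq) in enumerate(c.blocks):
            if k == len(c.blocks) - 1:
                out.append(str(size))
            else:
                out.append(f"{size} {dt} {dq}")
        out.append("")
    return "\n".join(out) + "\n"


def lift_interval(
    index: ChainIndex,
    interval: GenomicInterval,
    min_mapped_fraction: float = 0.95,
) -> LiftResult | LiftFailure:
    """Lift an interval through the best-scoring overlapping chain.

    Every base is mapped through the ungapped blocks of that single
    chain; the lifted interval is the forward-strand envelope of the
    mapped positions. Fails when no chain overlaps or too few bases map
    (bases reachable only through other chains do not count, so windows
    split across chains fail as unmappable).
    """
    candidates = index.overlapping(interval)
    if not candidates:
        return LiftFailure("no_ortholog", "no overlapping chain")
    best = max(candidates, key=lambda c: (c.score, -c.chain_id))
    base_map = best.map_interval_bases(interval.start, interval.end)
    fraction = len(base_map) / len(interval)
    if fraction < min_mapped_fraction:
        return LiftFailure(
            "no_ortholog",
            f"only {fraction:.2%} of bases map through chain {best.chain_id}",
        )
    lo = min(base_map.values())
    hi = max(base_map.values())
    lifted = GenomicInterval(best.q_name, lo, hi + 1, best.q_strand)
    return LiftResult(lifted, best, fraction, base_map)
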