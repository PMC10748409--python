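"""Final panel emission: per-SNP design windows and a target manifest.

Each unique selected SNP (proxy SNPs plus literature SNPs for the
target species) gets a design window of at most 120 bp centered on the
SNP, truncated at chromosome ends. Primer design itself is an external
step; an optional design-result table can mark targets as failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import GenomicInterval
from .liftover import chrom_length

MAX_WINDOW = 120


@dataclass
class PanelTarget:
    target_id: str
    rsid: str
    snp_chrom: str
    snp_pos: int  # 1-based
    design_window: GenomicInterval | None
    represented_loci: list[str]
    status: str  # designed | failed

    def __post_init__(self) -> None:
        if self.status not in ("designed", "failed"):
            raise ValueError(f"bad status {self.status!r}")
        if self.design_window is not None:
            if len(self.design_window) > MAX_WINDOW:
                raise ValueError("design window exceeds the maximum length")
            pos0 = self.snp_pos - 1
            if not (self.design_window.start <= pos0 < self.design_window.end):
                raise ValueError("design window does not contain the SNP")


def build_panel(
    proxy_snps: pd.DataFrame,
    literature_snps: pd.DataFrame,
    genome,
    window: int = MAX_WINDOW,
) -> tuple[list[PanelTarget], dict]:
    """One design target per unique SNP (proxy set + literature set).

    Input frames need columns ``rsid chrom pos`` (1-based); the proxy
    frame may carry ``represented_loci``. The window places the SNP at
    offset ``window // 2`` (left flank ``window // 2``, right flank
    ``window // 2 - 1``); windows are truncated at chromosome ends.
    SNPs whose coordinates fall off the genome yield failed targets and
    the run continues.
    """
    flank = window // 2
    seen: dict[tuple[str, int], PanelTarget] = {}
    order: list[tuple[str, int]] = []
    for df, is_proxy in ((proxy_snps, True), (literature_snps, False)):
        if df is None or df.empty:
            continue
        for row in df.itertuples(index=False):
            key = (str(row.chrom), int(row.pos))
            loci = []
            if is_proxy and hasattr(row, "represented_loci") and row.represented_loci:
                loci = str(row.represented_loci).split(",")
            if key in seen:
                seen[key].represented_loci.extend(
                    x for x in loci if x not in seen[key].represented_loci
                )
                continue
            order.append(key)
            chrom, pos = key
            rsid = str(row.rsid)
            try:
                clen = chrom_length(genome, chrom)
            except KeyError:
                clen = -1
            pos0 = pos - 1
            if clen < 0 or not (0 <= pos0 < clen):
                seen[key] = PanelTarget(
                    f"target_{len(order):04d}", rsid, chrom, pos, None, loci, "failed"
                )
                continue
            start = max(0, pos0 - flank)
            end = min(clen, pos0 + (window - flank))
            seen[key] = PanelTarget(
                f"target_{len(order):04d}",
                rsid,
                chrom,
                pos,
                GenomicInterval(chrom, start, end),
                loci,
                "designed",
            )
    targets = [seen[k] for k in order]
    designed = [t for t in targets if t.status == "designed"]
    per_chrom: dict[str, int] = {}
    for t in designed:
        per_chrom[t.snp_chrom] = per_chrom.get(t.snp_chrom, 0) + 1
    summary = {
        "n_targets": len(targets),
        "n_designed": len(designed),
        "n_failed": len(targets) - len(designed),
        "total_bases": sum(len(t.design_window) for t in designed),
        "per_chromosome": dict(sorted(per_chrom.items())),
    }
    return targets, summary


def apply_design_results(targets: list[PanelTarget], design_results: pd.DataFrame) -> None:
    """Mark targets failed per an external design-result table.

    The table needs columns ``target_id status`` with status
    designed/failed; unknown ids are ignored.
    """
    status = dict(
        design_results[["target_id", "status"]].itertuples(index=False)
    )
    for t in targets:
        if status.get(t.target_id) == "failed":
            t.status = "failed"
            t.design_window = None


def manifest_table(targets: list[PanelTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "rsid": t.rsid,
                "chrom": t.snp_chrom,
                "snp_pos": t.snp_pos,
                "window_start": t.design_window.start + 1 if t.design_window else 0,
                "window_end": t.design_window.end if t.design_window else 0,
                "represented_loci": ",".join(t.represented_loci),
                "status": t.status,
            }
            for t in targets
        ]
    )


def panel_bed(targets: list[PanelTarget]) -> pd.DataFrame:
    """0-based BED of designed windows; write -> read is the identity."""
    return pd.DataFrame(
        [
            {
                "chrom": t.design_window.chrom,
                "start": t.design_window.start,
                "end": t.design_window.end,
                "name": t.target_id,
            }
            for t in targets
            if t.status == "designed"
        ],
        columns=["chrom", "start", "end", "name"],
    )
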