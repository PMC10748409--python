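"""Merging curated SNP association tables into a non-redundant set.

Sources (database exports, literature curation) are tab-separated tables
with columns ``rsid chrom pos ref alt source species p``. Records
carrying an association p-value must pass p < 1e-5; records without one
(manually curated entries) are retained. Entries absent from a reference
SNP catalog are dropped.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd

from .core import SnpRecord

P_THRESHOLD = 1e-5

REQUIRED_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "source", "species", "p"]

_RS_RE = re.compile(r"^rs\d+$", re.IGNORECASE)


def normalize_rsid(rsid: str) -> str:
    """Case-insensitive canonical form; non-rs identifiers pass with a warning."""
    rsid = str(rsid).strip()
    if not rsid:
        raise ValueError("empty rsid")
    if not _RS_RE.match(rsid):
        warnings.warn(f"identifier {rsid!r} is not an rs number; passing through")
        return rsid
    return rsid.lower()


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _records_from_table(df: pd.DataFrame, origin: str = "<table>") -> list[SnpRecord]:
    records = []
    for i, row in df.iterrows():
        try:
            p = row.get("p")
            p = None if pd.isna(p) or str(p).strip() == "" else float(p)
            records.append(
                SnpRecord(
                    rsid=normalize_rsid(row["rsid"]),
                    chrom="" if pd.isna(row.get("chrom")) else str(row["chrom"]),
                    pos=0 if pd.isna(row.get("pos")) else int(row["pos"]),
                    ref_allele="" if pd.isna(row.get("ref")) else str(row["ref"]),
                    alt_allele="" if pd.isna(row.get("alt")) else str(row["alt"]),
                    sources=frozenset(str(row["source"]).split(",")),
                    species="" if pd.isna(row.get("species")) else str(row["species"]),
                    association_p=p,
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"{origin}, line {i + 2}: {e}") from e
    return records


def merge_sources(
    tables: list[pd.DataFrame],
    p_threshold: float = P_THRESHOLD,
    origins: list[str] | None = None,
) -> list[SnpRecord]:
    """Merge tables into one record per rsID.

    The association filter (p < threshold, strict) applies only to
    records that report a p-value; duplicates are collapsed with the
    union of their source tags, keeping the first non-missing
    coordinates and alleles.
    """
    origins = origins or [f"table {i}" for i in range(len(tables))]
    merged: dict[str, SnpRecord] = {}
    for df, origin in zip(tables, origins):
        for rec in _records_from_table(df, origin):
            if rec.association_p is not None and not rec.association_p < p_threshold:
                continue
            prev = merged.get(rec.rsid)
            if prev is None:
                merged[rec.rsid] = rec
            else:
                merged[rec.rsid] = SnpRecord(
                    rsid=prev.rsid,
                    chrom=prev.chrom or rec.chrom,
                    pos=prev.pos or rec.pos,
                    ref_allele=prev.ref_allele or rec.ref_allele,
                    alt_allele=prev.alt_allele or rec.alt_allele,
                    sources=prev.sources | rec.sources,
                    species=prev.species or rec.species,
                    association_p=(
                        prev.association_p
                        if prev.association_p is not None
                        else rec.association_p
                    ),
                )
    return sorted(merged.values(), key=lambda r: r.rsid)


def read_catalog(path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    col = "rsid" if "rsid" in df.columns else df.columns[0]
    return {normalize_rsid(r) for r in df[col].dropna()}


def filter_by_catalog(snps: list[SnpRecord], catalog: set[str]) -> list[SnpRecord]:
    """Keep only SNPs present in the reference catalog."""
    if not catalog:
        warnings.warn("empty SNP catalog: all records filtered out")
        return []
    catalog_norm = {normalize_rsid(r) for r in catalog}
    return [s for s in snps if s.rsid in catalog_norm]


def records_to_table(records: list[SnpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_allele,
                "alt": r.alt_allele,
                "source": ",".join(sorted(r.sources)),
                "species": r.species,
                "p": "" if r.association_p is None else r.association_p,
            }
            for r in records
        ],
        columns=REQUIRED_COLUMNS[:5] + ["source", "species", "p"],
    )
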