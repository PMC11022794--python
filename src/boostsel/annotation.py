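"""SNP-to-gene mapping with flanking regions from GFF3 gene models.

A SNP hits a gene when it lies within the gene body or within ``flank``
basepairs of either end (closed intervals, 1-based inclusive
coordinates).  The relation of a flank hit (upstream vs downstream) is
taken relative to the gene's strand.  One SNP may hit several
overlapping genes; the candidate table reports both SNP-level and
gene-level granularity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genotype import VariantSite

__all__ = [
    "GeneModel",
    "GeneHit",
    "read_gff",
    "map_snps_to_genes",
    "candidate_table",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class GeneHit:
    site_id: str
    gene_id: str
    relation: str  # within | upstream-flank | downstream-flank
    distance: int  # bp from the nearest gene boundary; 0 iff within


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene features from a GFF3 file (non-gene features ignored)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(GeneModel(gene_id=gid, chrom=feat.seqid,
                               start=feat.start, end=feat.end, strand=strand))
    return genes


def _relation(pos: int, gene: GeneModel) -> tuple[str, int]:
    if gene.start <= pos <= gene.end:
        return "within", 0
    if pos < gene.start:
        dist = gene.start - pos
        side_is_5prime = gene.strand == "+"
    else:
        dist = pos - gene.end
        side_is_5prime = gene.strand == "-"
    return ("upstream-flank" if side_is_5prime else "downstream-flank"), dist


def map_snps_to_genes(
    sites: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    flank: int = 1000,
) -> list[GeneHit]:
    """All (site, gene) hits within the gene body or its flanks.

    Boundaries are inclusive: a SNP exactly ``flank`` bp from a gene end
    still hits.  Hits are sorted by (chrom, pos, gene id).  Lookup is a
    per-chromosome sorted-interval sweep; semantics are identical to the
    brute-force scan over all pairs.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start - flank, g.end))
    hits: list[GeneHit] = []
    for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
        for gene in by_chrom.get(site.chrom, ()):
            if gene.start - flank > site.pos:
                break
            if site.pos <= gene.end + flank:
                relation, dist = _relation(site.pos, gene)
                hits.append(GeneHit(site_id=site.site_id, gene_id=gene.gene_id,
                                    relation=relation, distance=dist))
    hits.sort(key=lambda h: (h.site_id.split(":")[0],
                             int(h.site_id.split(":")[1]), h.gene_id))
    return hits


def candidate_table(
    hits: Iterable[GeneHit],
    model_counts: dict[str, int] | None = None,
    functional_annotation: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per hit gene: SNP count, best replicate support, relations.

    ``model_counts`` maps site ids to the number of replicate models that
    scored the site important (collinear additions count 0).
    """
    rows: dict[str, dict] = {}
    for h in hits:
        row = rows.setdefault(h.gene_id, {
            "gene_id": h.gene_id, "snp_count": 0, "best_model_count": 0,
            "relations": set(), "snps": [],
        })
        row["snp_count"] += 1
        row["snps"].append(h.site_id)
        row["relations"].add(h.relation)
        if model_counts:
            row["best_model_count"] = max(
                row["best_model_count"], model_counts.get(h.site_id, 0)
            )
    records = []
    for gid in sorted(rows):
        row = rows[gid]
        rec = {
            "gene_id": gid,
            "snp_count": row["snp_count"],
            "best_model_count": row["best_model_count"],
            "relations": ",".join(sorted(row["relations"])),
            "snps": ",".join(row["snps"]),
        }
        if functional_annotation is not None:
            rec["annotation"] = functional_annotation.get(gid, "")
        records.append(rec)
    columns = ["gene_id", "snp_count", "best_model_count", "relations", "snps"]
    if functional_annotation is not None:
        columns.append("annotation")
    return pd.DataFrame(records, columns=columns)
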