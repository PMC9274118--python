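"""GWAS result post-processing: SNP filters, consensus sets, gene annotation.

The upstream association scans (six multi-locus mixed-model methods) are
external; this module consumes their per-method result tables.  It
provides the genotype quality filters (minor allele frequency and call
rate), the two-step significance screen (genome-wide pre-filter at
p <= 0.5/N followed by the final threshold p <= 2e-4), the Top1 /
multi-method consensus construction, SNP-to-gene annotation against a
GFF3, and export of the trait–gene–pathway network as node/edge tables
and SIF.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "SnpSummary", "ConsensusSets", "GeneHit",
    "snp_summaries", "filter_snps", "significance_filter", "consensus",
    "load_genes", "annotate", "trait_gene_edges", "export_network",
    "write_sif", "parse_sif", "ASSOC_COLUMNS",
]

ASSOC_COLUMNS = ["snp_id", "chrom", "pos", "trait", "method",
                 "p_value", "effect", "pve"]


@dataclass
class SnpSummary:
    snp_id: str
    chrom: str
    pos: int
    maf: float
    call_rate: float


@dataclass
class ConsensusSets:
    """Per-trait consensus of significant SNPs across methods."""

    top1: dict[str, str]          # method -> snp_id
    multi: set[str]               # snp_ids found by >= 2 methods
    high_confidence: set[str] = field(init=False)
    both: set[str] = field(init=False)

    def __post_init__(self) -> None:
        top = set(self.top1.values())
        self.high_confidence = top | self.multi
        self.both = top & self.multi


@dataclass
class GeneHit:
    gene_id: str
    description: str
    chrom: str
    start: int
    end: int
    relation: str     # within | upstream | downstream
    distance_bp: int


def snp_summaries(genotypes: pd.DataFrame, positions: pd.DataFrame | None = None
                  ) -> list[SnpSummary]:
    """Per-SNP minor-allele frequency and call rate.

    ``genotypes`` has one row per SNP (index = snp_id) and one column per
    line, coded 0/1/2 with NaN for missing.  ``positions`` optionally maps
    snp_id to chrom/pos.  SNPs with all calls missing have no defined MAF
    and are excluded with a warning.
    """
    out: list[SnpSummary] = []
    vals = genotypes.to_numpy(dtype=float)
    skipped = []
    for i, snp in enumerate(genotypes.index):
        row = vals[i]
        ok = np.isfinite(row)
        call_rate = float(ok.mean()) if row.size else 0.0
        if not ok.any():
            skipped.append(snp)
            continue
        f = float(row[ok].mean() / 2.0)
        chrom, pos = "", 0
        if positions is not None and snp in positions.index:
            chrom = str(positions.loc[snp, "chrom"])
            pos = int(positions.loc[snp, "pos"])
        out.append(SnpSummary(snp_id=str(snp), chrom=chrom, pos=pos,
                              maf=min(f, 1.0 - f), call_rate=call_rate))
    if skipped:
        warnings.warn(f"{len(skipped)} SNPs with all calls missing excluded",
                      stacklevel=2)
    return out


def filter_snps(summaries: list[SnpSummary], maf_min: float = 0.05,
                callrate_min: float = 0.9) -> list[str]:
    """Keep SNPs with maf strictly above ``maf_min`` and call rate strictly
    above ``callrate_min`` (both cut-offs exclusive, as conventionally
    applied)."""
    return [s.snp_id for s in summaries
            if s.maf > maf_min and s.call_rate > callrate_min]


def significance_filter(
    records: pd.DataFrame,
    n_snps: int,
    screen_factor: float = 0.5,
    final_p: float = 0.0002,
) -> tuple[pd.DataFrame, float]:
    """Two-step significance screen of association records.

    Stage 1 keeps p <= screen_factor / n_snps (the genome-wide pre-filter
    each multi-locus method applies to single-marker scans); stage 2 keeps
    p <= final_p.  Returns the surviving records and the effective stage-1
    cut-off.  Records with non-positive p-values are malformed.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if (records["p_value"] <= 0).any():
        raise ValueError("malformed records: p_value must be in (0, 1]")
    cutoff = screen_factor / n_snps
    kept = records[(records["p_value"] <= cutoff)
                   & (records["p_value"] <= final_p)].copy()
    return kept, cutoff


def consensus(records: pd.DataFrame) -> dict[str, ConsensusSets]:
    """Top1 and multi-method consensus per trait.

    ``records`` are already significance-filtered.  For each trait and
    method, Top1 is the record of minimal p (ties break to the lower
    (chrom, pos) coordinate); ``multi`` contains SNPs reported by at least
    two distinct methods for the same trait.
    """
    out: dict[str, ConsensusSets] = {}
    for trait, sub in records.groupby("trait"):
        top1: dict[str, str] = {}
        for method, msub in sub.groupby("method"):
            best = msub.sort_values(["p_value", "chrom", "pos"],
                                    kind="mergesort").iloc[0]
            top1[str(method)] = str(best["snp_id"])
        by_methods = sub.groupby("snp_id")["method"].nunique()
        multi = set(by_methods[by_methods >= 2].index.astype(str))
        out[str(trait)] = ConsensusSets(top1=top1, multi=multi)
    return out


def load_genes(gff3_path: str | os.PathLike) -> pd.DataFrame:
    """Gene features from a GFF3 as a table (gene_id, description, chrom,
    start, end), via an in-memory gffutils database."""
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for g in db.features_of_type("gene"):
        desc = (g.attributes.get("description") or g.attributes.get("Name")
                or [g.id])[0]
        rows.append({"gene_id": g.id, "description": desc, "chrom": g.seqid,
                     "start": int(g.start), "end": int(g.end)})
    return pd.DataFrame(rows)


def annotate(
    snps: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 10_000
) -> dict[str, list[GeneHit]]:
    """Assign each SNP to genes from the annotation table.

    A gene whose 1-based inclusive [start, end] span contains the SNP
    position yields a ``within`` hit at distance 0; otherwise genes within
    ``window_bp`` on either side yield ``upstream`` (SNP before the gene
    start) or ``downstream`` (SNP past the gene end) hits.  Hits are
    ordered by distance then gene_id.  SNPs on chromosomes absent from
    the annotation are recorded with no hits, with a warning.
    """
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    out: dict[str, list[GeneHit]] = {}
    missing_chroms = set()
    for _, snp in snps.iterrows():
        chrom, pos, sid = str(snp["chrom"]), int(snp["pos"]), str(snp["snp_id"])
        hits: list[GeneHit] = []
        tab = by_chrom.get(chrom)
        if tab is None:
            missing_chroms.add(chrom)
            out[sid] = hits
            continue
        start = tab["start"].to_numpy()
        end = tab["end"].to_numpy()
        dist = np.where(pos < start, start - pos,
                        np.where(pos > end, pos - end, 0))
        for j in np.flatnonzero(dist <= window_bp):
            if dist[j] == 0:
                rel = "within"
            elif pos < start[j]:
                rel = "upstream"
            else:
                rel = "downstream"
            row = tab.iloc[j]
            hits.append(GeneHit(gene_id=str(row["gene_id"]),
                                description=str(row["description"]),
                                chrom=chrom, start=int(row["start"]),
                                end=int(row["end"]), relation=rel,
                                distance_bp=int(dist[j])))
        hits.sort(key=lambda h: (h.distance_bp, h.gene_id))
        out[sid] = hits
    if missing_chroms:
        warnings.warn("SNP chromosomes absent from annotation: "
                      f"{sorted(missing_chroms)}", stacklevel=2)
    return out


def trait_gene_edges(
    consensus_by_trait: dict[str, ConsensusSets],
    assignment: dict[str, list[GeneHit]],
    which: str = "high_confidence",
) -> pd.DataFrame:
    """Trait-to-gene edges from consensus SNPs and their gene hits."""
    rows = []
    for trait, sets in consensus_by_trait.items():
        for snp in sorted(getattr(sets, which)):
            for hit in assignment.get(snp, []):
                rows.append({"trait": trait, "gene_id": hit.gene_id,
                             "snp_id": snp, "relation": hit.relation})
    return pd.DataFrame(rows, columns=["trait", "gene_id", "snp_id", "relation"]
                        ).drop_duplicates(["trait", "gene_id"]).reset_index(drop=True)


def export_network(
    edges: pd.DataFrame,
    gene_pathways: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the trait–gene(–pathway) network.

    ``edges`` has columns trait, gene_id; ``gene_pathways`` optionally has
    gene_id, pathway.  Nodes are deduplicated across roles; the edge table
    carries an interaction label (``associates`` for trait–gene,
    ``member_of`` for gene–pathway) suitable for SIF export.
    """
    node_rows: list[dict] = []
    seen: set[str] = set()

    def add(node: str, ntype: str) -> None:
        if node not in seen:
            seen.add(node)
            node_rows.append({"id": node, "type": ntype})

    edge_rows = []
    for _, e in edges.iterrows():
        add(str(e["trait"]), "trait")
        add(str(e["gene_id"]), "gene")
        edge_rows.append({"source": str(e["trait"]), "interaction": "associates",
                          "target": str(e["gene_id"])})
    if gene_pathways is not None:
        for _, e in gene_pathways.iterrows():
            add(str(e["gene_id"]), "gene")
            add(str(e["pathway"]), "pathway")
            edge_rows.append({"source": str(e["gene_id"]),
                              "interaction": "member_of",
                              "target": str(e["pathway"])})
    nodes = pd.DataFrame(node_rows, columns=["id", "type"])
    out_edges = pd.DataFrame(edge_rows,
                             columns=["source", "interaction", "target"]
                             ).drop_duplicates().reset_index(drop=True)
    return nodes, out_edges


def write_sif(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for _, e in edges.iterrows():
            fh.write(f"{e['source']}\t{e['interaction']}\t{e['target']}\n")


def parse_sif(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                rows.append({"source": parts[0], "interaction": parts[1],
                             "target": parts[2]})
    return pd.DataFrame(rows, columns=["source", "interaction", "target"])
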