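"""lncRNA genomic-context classification and cis coding-gene linkage.

lncRNAs are classified relative to coding-gene models into intergenic,
exon-/intron-overlapping, natural/intronic antisense and bidirectional
classes, then linked to coding genes on the same chromosome within a fixed
window (300 kb) as candidate cis-regulatory neighbors.  All coordinates
are 0-based half-open (BED convention); the gap between [a,b) and [c,d)
with c >= b is c - b, 0 for touching or overlapping intervals, and links
use an inclusive <= window.

Classification precedence (one class per lncRNA): exon-overlap >
intron-overlap > natural antisense > intronic antisense > bidirectional >
intergenic.  "Bidirectional" means no gene overlap and a divergent
opposite-strand transcription start site within 1 kb (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 300_000
DEFAULT_BIDIRECTIONAL_DISTANCE = 1_000

CLASS_PRECEDENCE = (
    "exon-overlap",
    "intron-overlap",
    "natural-antisense",
    "intronic-antisense",
    "bidirectional",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A coding gene: interval, strand, and sorted non-overlapping exons."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.symbol}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.symbol}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.symbol}: at least one exon required")
        prev = self.start
        for s, e in self.exons:
            if s < prev and prev is not self.start:
                raise ValueError(f"{self.symbol}: exons must be sorted, non-overlapping")
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"{self.symbol}: exon outside gene bounds")
            prev = e

    @property
    def tss(self) -> int:
        """Transcription start: left edge on +, right edge on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class CisLink:
    lncrna_id: str
    gene_symbol: str
    distance: int
    relation: str


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def genes_by_chromosome(gene_models) -> dict[str, list[GeneModel]]:
    """Per-chromosome gene lists sorted by start coordinate."""
    by: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by.setdefault(g.chrom, []).append(g)
    for chrom in by:
        by[chrom].sort(key=lambda g: (g.start, g.end, g.symbol))
    return by


def classify_context(chrom: str, start: int, end: int, strand: str,
                     genes: dict[str, list[GeneModel]] | list,
                     bidirectional_distance: int = DEFAULT_BIDIRECTIONAL_DISTANCE) -> str:
    """Single genomic context class for one lncRNA interval.

    ``genes`` may be a list of GeneModel or the dict from
    :func:`genes_by_chromosome`.  An lncRNA on a chromosome with no gene
    models is intergenic (with a warning).
    """
    if not isinstance(genes, dict):
        genes = genes_by_chromosome(genes)
    models = genes.get(chrom)
    if not models:
        logger.warning("lncRNA on chromosome %r with no gene models: intergenic", chrom)
        return "intergenic"

    same_exon = same_body = anti_exon = anti_body = False
    bidirectional = False
    tss = start if strand == "+" else end
    for g in models:
        overlap = _overlaps(start, end, g.start, g.end)
        exon_hit = overlap and any(_overlaps(start, end, es, ee) for es, ee in g.exons)
        contained = g.start <= start and end <= g.end
        if g.strand == strand:
            same_exon |= exon_hit
            same_body |= contained and not exon_hit
        else:
            anti_exon |= exon_hit
            anti_body |= contained and not exon_hit
        if not overlap and g.strand != strand:
            if abs(tss - g.tss) <= bidirectional_distance:
                plus_tss = tss if strand == "+" else g.tss
                minus_tss = g.tss if strand == "+" else tss
                if minus_tss <= plus_tss:  # divergent orientation
                    bidirectional = True
    # a partial overlap with any gene excludes the bidirectional class
    any_overlap = any(_overlaps(start, end, g.start, g.end) for g in models)

    if same_exon:
        return "exon-overlap"
    if same_body:
        return "intron-overlap"
    if anti_exon:
        return "natural-antisense"
    if anti_body:
        return "intronic-antisense"
    if bidirectional and not any_overlap:
        return "bidirectional"
    return "intergenic"


def classify_all(annotation: pd.DataFrame, gene_models,
                 bidirectional_distance: int = DEFAULT_BIDIRECTIONAL_DISTANCE) -> pd.DataFrame:
    """Context class for every lncRNA probe in the annotation table."""
    by = genes_by_chromosome(gene_models)
    lnc = annotation[annotation["rna_class"] == "lncRNA"]
    classes = [classify_context(r.chrom, r.start, r.end, r.strand, by,
                                bidirectional_distance)
               for r in lnc.itertuples()]
    out = lnc[["transcript_id", "chrom", "start", "end", "strand"]].copy()
    out["context_class"] = classes
    out.attrs["precedence"] = CLASS_PRECEDENCE
    return out.reset_index(drop=True)


def interval_gap(a_start, a_end, b_start, b_end) -> int:
    """bp gap between two half-open intervals; 0 when touching/overlapping."""
    return max(b_start - a_end, a_start - b_end, 0)


def find_cis_genes(lncrna_id: str, chrom: str, start: int, end: int,
                   genes: dict[str, list[GeneModel]] | list,
                   window: int = DEFAULT_WINDOW,
                   relation: str = ".") -> list[CisLink]:
    """All same-chromosome coding genes with boundary gap <= window,
    sorted by distance then symbol."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not isinstance(genes, dict):
        genes = genes_by_chromosome(genes)
    links = []
    for g in genes.get(chrom, []):
        gap = interval_gap(start, end, g.start, g.end)
        if gap <= window:
            links.append(CisLink(lncrna_id, g.symbol, gap, relation))
    links.sort(key=lambda l: (l.distance, l.gene_symbol))
    return links


def cis_link_table(annotation: pd.DataFrame, gene_models,
                   window: int = DEFAULT_WINDOW,
                   bidirectional_distance: int = DEFAULT_BIDIRECTIONAL_DISTANCE) -> pd.DataFrame:
    """cis links for every lncRNA, with its context class as the relation."""
    by = genes_by_chromosome(gene_models)
    ctx = classify_all(annotation, gene_models, bidirectional_distance)
    ctx_of = dict(zip(ctx["transcript_id"], ctx["context_class"]))
    rows = []
    for r in annotation[annotation["rna_class"] == "lncRNA"].itertuples():
        for link in find_cis_genes(r.transcript_id, r.chrom, r.start, r.end, by,
                                   window, relation=ctx_of[r.transcript_id]):
            rows.append({"lncrna_id": link.lncrna_id, "gene_symbol": link.gene_symbol,
                         "distance": link.distance, "relation": link.relation})
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_symbol", "distance", "relation"])


def link_to_de(cis_links: pd.DataFrame, expression_records: pd.DataFrame):
    """Intersect cis links with up/down expression calls.

    Returns ``(table, de_gene_set, n_lncrnas_with_de)``: the filtered link
    table with the neighbor's call attached, the deduplicated DE gene-symbol
    set (enrichment input), and the count of lncRNAs with >= 1 DE neighbor.
    """
    de = expression_records.loc[expression_records["call"].isin(["up", "down"]),
                                ["gene_symbol", "call"]].drop_duplicates("gene_symbol")
    if cis_links.empty or de.empty:
        empty = cis_links.iloc[0:0].assign(call=pd.Series(dtype=object))
        return empty, set(), 0
    table = cis_links.merge(de, on="gene_symbol", how="inner")
    table = table.sort_values(["lncrna_id", "distance", "gene_symbol"]).reset_index(drop=True)
    return table, set(table["gene_symbol"]), int(table["lncrna_id"].nunique())


def select_signflip_lncrnas(meth_records_a: pd.DataFrame,
                            meth_records_b: pd.DataFrame):
    """lncRNAs whose methylation call flips sign between two comparisons.

    Returns ``(hyper_in_a_hypo_in_b, hypo_in_a_hyper_in_b)`` as sets of
    transcript ids restricted to rna_class == 'lncRNA'.
    """
    def calls(records, call):
        mask = (records["rna_class"] == "lncRNA") & (records["call"] == call)
        return set(records.loc[mask, "transcript_id"])

    hyper_a, hypo_a = calls(meth_records_a, "hyper"), calls(meth_records_a, "hypo")
    hyper_b, hypo_b = calls(meth_records_b, "hyper"), calls(meth_records_b, "hypo")
    return hyper_a & hypo_b, hypo_a & hyper_b
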