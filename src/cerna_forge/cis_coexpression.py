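"""cis co-expression pairing of DE lncRNAs with DE protein-coding genes.

A differentially expressed lncRNA is paired with every differentially
expressed coding gene on the same chromosome whose genomic interval lies
within 100 kb of it ("100 kb upstream and downstream", inclusive at exactly
the window). Distance is measured between the nearest interval ends
(overlap = 0) and signed negative when the lncRNA lies upstream of the gene
relative to the gene's strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import AnnotationSet

__all__ = ["CisEdge", "cis_pairs", "degree_summary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CisEdge:
    lncrna_id: str
    mrna_id: str
    distance: int  # signed; 0 when intervals overlap; negative = lncRNA upstream
    chrom: str


def _gene_spans(annotation: AnnotationSet, keep: set[str]):
    spans = []
    for gid, (chrom, strand, start, end) in sorted(annotation.genes().items()):
        if gid in keep:
            spans.append((gid, chrom, strand, start, end))
    return spans


def cis_pairs(
    lncrnas: AnnotationSet,
    genes: AnnotationSet,
    de_lncrnas: set[str],
    de_genes: set[str],
    window: int = 100_000,
) -> list[CisEdge]:
    """All (DE lncRNA, DE gene) pairs with interval gap <= window, same chromosome.

    ``de_lncrnas``/``de_genes`` are gene-level identifier sets (features
    missing from the annotation are skipped with a warning). The boundary is
    inclusive: a gap of exactly ``window`` still forms an edge.
    """
    lnc_spans = _gene_spans(lncrnas, de_lncrnas)
    gene_spans = _gene_spans(genes, de_genes)
    for wanted, got, label in (
        (de_lncrnas, {g[0] for g in lnc_spans}, "lncRNA"),
        (de_genes, {g[0] for g in gene_spans}, "gene"),
    ):
        for missing in sorted(wanted - got):
            log.warning("DE %s %s has no coordinates; skipped", label, missing)
    by_chrom: dict[str, list] = {}
    for g in gene_spans:
        by_chrom.setdefault(g[1], []).append(g)
    edges: list[CisEdge] = []
    for lid, lchrom, _lstrand, ls, le in lnc_spans:
        for gid, _chrom, gstrand, gs, ge in by_chrom.get(lchrom, []):
            if le <= gs:
                gap = gs - le
            elif ge <= ls:
                gap = ls - ge
            else:
                gap = 0
            if gap > window:
                continue
            # sign: negative when the lncRNA is upstream of the gene,
            # relative to the gene's transcription direction
            if gap == 0:
                dist = 0
            elif gstrand == "+":
                dist = -gap if le <= gs else gap
            else:
                dist = -gap if ge <= ls else gap
            edges.append(CisEdge(lid, gid, dist, lchrom))
    edges.sort(key=lambda e: (e.lncrna_id, e.mrna_id))
    return edges


def degree_summary(edges: list[CisEdge], min_degree: int = 1) -> pd.DataFrame:
    """lncRNAs ranked by the number of distinct interacting mRNAs.

    Descending degree, ties broken lexicographically by identifier.
    """
    if not edges:
        return pd.DataFrame(columns=["lncrna_id", "degree"])
    df = pd.DataFrame([(e.lncrna_id, e.mrna_id) for e in edges],
                      columns=["lncrna_id", "mrna_id"])
    deg = (
        df.drop_duplicates()
        .groupby("lncrna_id")["mrna_id"]
        .size()
        .reset_index(name="degree")
    )
    deg = deg[deg["degree"] >= min_degree]
    deg = deg.sort_values(
        ["degree", "lncrna_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return deg
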