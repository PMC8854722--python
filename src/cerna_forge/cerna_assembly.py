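"""ceRNA network assembly from target sites, sponge sites and DE calls.

Edges are typed miRNA-partner pairs (miRNA-mRNA from duplex target
prediction, miRNA-lncRNA and miRNA-circRNA from sponge matching), restricted
to pairs where both endpoints are differentially expressed. Triads
(ceRNA, miRNA, mRNA) are materialized wherever a sponge edge and a target
edge share a miRNA — "common miRNA binding". The triad count therefore
equals sum over miRNAs of sponges(m) * targets(m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .io_formats import write_network_graphml, write_network_sif
from .sponge_matcher import SpongeSite
from .target_scoring import DuplexAlignment

__all__ = ["CeRNAEdge", "CeRNATriad", "build_edges", "build_triads", "export_network"]

EDGE_TYPES = {"mRNA": "miRNA-mRNA", "lncRNA": "miRNA-lncRNA", "circRNA": "miRNA-circRNA"}


@dataclass(frozen=True)
class CeRNAEdge:
    mirna_id: str
    partner_id: str
    partner_class: str  # "mRNA" | "lncRNA" | "circRNA"
    n_sites: int
    best_score: float | None  # lowest duplex penalty; None for sponge edges


@dataclass(frozen=True)
class CeRNATriad:
    cerna_id: str
    cerna_class: str
    mirna_id: str
    mrna_id: str


def build_edges(
    target_sites: list[DuplexAlignment],
    sponge_sites: list[SpongeSite],
    de_mirnas: set[str],
    de_partners: dict[str, set[str]],
) -> list[CeRNAEdge]:
    """Typed, deduplicated miRNA-partner edges restricted to DE endpoints.

    ``de_partners`` maps each partner class ("mRNA", "lncRNA", "circRNA") to
    its set of DE feature identifiers. A site naming a partner class with no
    DE set is an error (unknown feature provenance).
    """
    for cls in ("mRNA", "lncRNA", "circRNA"):
        de_partners.setdefault(cls, set())
    grouped: dict[tuple[str, str, str], list[float | None]] = {}
    for site in target_sites:
        grouped.setdefault((site.mirna_id, site.target_id, "mRNA"), []).append(
            site.score
        )
    for site in sponge_sites:
        if site.ncrna_class not in ("lncRNA", "circRNA"):
            raise ValueError(
                f"sponge site references unknown class {site.ncrna_class!r}"
            )
        grouped.setdefault(
            (site.mirna_id, site.ncrna_id, site.ncrna_class), []
        ).append(None)
    edges = []
    for (mirna, partner, cls), scores in grouped.items():
        if mirna not in de_mirnas or partner not in de_partners[cls]:
            continue
        real = [s for s in scores if s is not None]
        edges.append(
            CeRNAEdge(
                mirna_id=mirna,
                partner_id=partner,
                partner_class=cls,
                n_sites=len(scores),
                best_score=min(real) if real else None,
            )
        )
    edges.sort(key=lambda e: (e.partner_class, e.mirna_id, e.partner_id))
    return edges


def edge_partition(edges: list[CeRNAEdge]) -> dict[str, int]:
    """Counts per edge type, in the miRNA-mRNA / miRNA-lncRNA / miRNA-circRNA partition."""
    out = {v: 0 for v in EDGE_TYPES.values()}
    for e in edges:
        out[EDGE_TYPES[e.partner_class]] += 1
    out["total"] = len(edges)
    return out


def build_triads(edges: list[CeRNAEdge]) -> list[CeRNATriad]:
    """All (ceRNA, miRNA, mRNA) triples joined on a common miRNA."""
    targets: dict[str, list[str]] = {}
    sponges: dict[str, list[tuple[str, str]]] = {}
    for e in edges:
        if e.partner_class == "mRNA":
            targets.setdefault(e.mirna_id, []).append(e.partner_id)
        else:
            sponges.setdefault(e.mirna_id, []).append((e.partner_id, e.partner_class))
    triads = [
        CeRNATriad(cid, ccls, m, g)
        for m in sorted(set(targets) & set(sponges))
        for cid, ccls in sorted(sponges[m])
        for g in sorted(targets[m])
    ]
    triads.sort(key=lambda t: (t.cerna_id, t.mirna_id, t.mrna_id))
    return triads


def export_network(
    edges: list[CeRNAEdge],
    triads: list[CeRNATriad],
    out_prefix,
    node_classes: dict[str, str] | None = None,
) -> dict:
    """Write edges.tsv, triads.tsv, network.sif, network.graphml, summary.json.

    Returns the summary dict (edge partition plus node/triad counts). Output
    is byte-deterministic for identical input.
    """
    out_prefix = str(out_prefix)
    with open(out_prefix + "edges.tsv", "w") as fh:
        fh.write("mirna_id\tpartner_id\tpartner_class\tn_sites\tbest_score\n")
        for e in sorted(edges, key=lambda e: (e.mirna_id, e.partner_id)):
            score = "" if e.best_score is None else f"{e.best_score:g}"
            fh.write(
                f"{e.mirna_id}\t{e.partner_id}\t{e.partner_class}\t{e.n_sites}\t{score}\n"
            )
    with open(out_prefix + "triads.tsv", "w") as fh:
        fh.write("cerna_id\tcerna_class\tmirna_id\tmrna_id\n")
        for t in triads:
            fh.write(f"{t.cerna_id}\t{t.cerna_class}\t{t.mirna_id}\t{t.mrna_id}\n")
    sif_edges = [
        (e.mirna_id, EDGE_TYPES[e.partner_class], e.partner_id) for e in edges
    ]
    write_network_sif(sif_edges, out_prefix + "network.sif")
    node_attrs = {}
    for e in edges:
        node_attrs[e.mirna_id] = {"rna_class": "miRNA"}
        node_attrs[e.partner_id] = {"rna_class": e.partner_class}
    if node_classes:
        for node, cls in node_classes.items():
            node_attrs.setdefault(node, {})["rna_class"] = cls
    write_network_graphml(sif_edges, out_prefix + "network.graphml", node_attrs)
    summary = {
        "edges": edge_partition(edges),
        "n_nodes": len(node_attrs),
        "n_triads": len(triads),
    }
    with open(out_prefix + "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
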