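"""circRNA calling from back-splice junction read evidence.

The caller consumes a plain table of junction-supporting reads (one row per
chimeric read: chromosome, strand, acceptor, donor, per-read alignment
mismatches) and applies three acceptance criteria:

1. per-read mismatches <= 2 (reads failing this are discarded before any
   grouping),
2. back-spliced junction reads >= 1,
3. genomic distance between the two splice sites < 100 kb (strict).

Calls are classified against the annotation as full-exon (both boundaries on
exon edges of one gene), exon-intron (inside a gene otherwise) or intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import AnnotationSet, FormatError

__all__ = [
    "JunctionEvidence",
    "BacksplicedJunction",
    "read_junction_evidence",
    "call_circrnas",
    "classify_circ_type",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionEvidence:
    """One chimeric read supporting a back-splice junction.

    ``acceptor`` < ``donor`` in genomic coordinates for a back-splice (the
    read joins the downstream donor back to the upstream acceptor);
    coordinates are 0-based half-open over [acceptor, donor).
    """

    read_id: str
    chrom: str
    strand: str
    acceptor: int
    donor: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass
class BacksplicedJunction:
    """One circRNA call with its supporting-read summary."""

    circ_id: str
    chrom: str
    strand: str
    start: int  # acceptor
    end: int    # donor
    supporting_reads: int
    max_mismatch_in_support: int
    circ_type: str = "unclassified"

    @property
    def span(self) -> int:
        return self.end - self.start


def read_junction_evidence(path) -> list[JunctionEvidence]:
    """Read the junction-evidence TSV (read_id, chrom, strand, acceptor, donor, mismatches)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["read_id", "chrom", "strand", "acceptor", "donor", "mismatches"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        JunctionEvidence(
            read_id=str(r.read_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            acceptor=int(r.acceptor),
            donor=int(r.donor),
            mismatches=int(r.mismatches),
        )
        for r in df.itertuples()
    ]


def call_circrnas(
    evidence: list[JunctionEvidence],
    max_mismatch: int = 2,
    min_reads: int = 1,
    max_span: int = 100_000,
) -> list[BacksplicedJunction]:
    """Apply the three circRNA acceptance criteria to junction evidence.

    Reads with too many mismatches are discarded before grouping; groups are
    keyed by (chrom, strand, acceptor, donor); groups with fewer than
    ``min_reads`` survivors or span >= ``max_span`` are dropped. Output is
    sorted by coordinate and named ``circRNA1..n`` in that order, so calls
    are invariant under evidence shuffling.
    """
    groups: dict[tuple[str, str, int, int], list[JunctionEvidence]] = {}
    for ev in evidence:
        if ev.donor - ev.acceptor <= 0:
            log.warning(
                "read %s: non-positive span (forward splice?); rejected", ev.read_id
            )
            continue
        if ev.mismatches > max_mismatch:
            continue
        groups.setdefault((ev.chrom, ev.strand, ev.acceptor, ev.donor), []).append(ev)
    calls: list[BacksplicedJunction] = []
    for (chrom, strand, acc, don), reads in groups.items():
        if len(reads) < min_reads:
            continue
        if don - acc >= max_span:
            continue
        calls.append(
            BacksplicedJunction(
                circ_id="",
                chrom=chrom,
                strand=strand,
                start=acc,
                end=don,
                supporting_reads=len(reads),
                max_mismatch_in_support=max(r.mismatches for r in reads),
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    for n, c in enumerate(calls, start=1):
        c.circ_id = f"circRNA{n}"
    return calls


def classify_circ_type(
    call: BacksplicedJunction,
    annotation: AnnotationSet,
    boundary_tolerance: int = 0,
) -> str:
    """Classify one call as full_exon, exon_intron or intergenic.

    full_exon: both call boundaries coincide (within the tolerance) with exon
    boundaries of one gene on the call's chromosome and the call lies within
    that gene's span. exon_intron: the call overlaps a gene otherwise.
    intergenic: no gene overlap.
    """
    overlapping = False
    for tx in annotation:
        if tx.chrom != call.chrom:
            continue
        if tx.end <= call.start or call.end <= tx.start:
            continue
        overlapping = True
        starts = {s for s, _ in tx.exons}
        ends = {e for _, e in tx.exons}
        start_ok = any(abs(call.start - s) <= boundary_tolerance for s in starts)
        end_ok = any(abs(call.end - e) <= boundary_tolerance for e in ends)
        if start_ok and end_ok and tx.start <= call.start and call.end <= tx.end:
            return "full_exon"
    return "exon_intron" if overlapping else "intergenic"


def calls_to_frame(calls: list[BacksplicedJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circRNA_id": c.circ_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "n_reads": c.supporting_reads,
                "max_mm": c.max_mismatch_in_support,
                "span": c.span,
                "circ_type": c.circ_type,
            }
            for c in calls
        ],
        columns=[
            "circRNA_id", "chrom", "start", "end", "strand",
            "n_reads", "max_mm", "span", "circ_type",
        ],
    )
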