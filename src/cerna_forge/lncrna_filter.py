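"""lncRNA candidate classification and filtering.

Assembled transcripts are compared against the reference annotation and given
a one-letter class code describing the overlap relation (``=`` exact match,
``j`` shared splice junction, ``o`` other same-strand exonic overlap, ``i``
intronic, ``x`` antisense exonic overlap, ``u`` intergenic). Candidates are
then filtered in three documented steps:

1. length >= 200 bp (summed over exons),
2. class code in {i, j, o, u, x} (i.e. transcripts overlapping known mRNAs
   sensu ``=`` are discarded),
3. a coding-potential predicate over supplied CNCI-like and CPC-like scores.

The deletion predicate is configurable: ``convention="literal"`` deletes
transcripts with CNCI score < 0 and CPC score < -1, exactly as the source
protocol prints it; ``convention="standard"`` deletes transcripts that look
coding under the usual sign convention (CNCI >= 0 or CPC >= -1, i.e. it
keeps only conventionally non-coding transcripts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AnnotationSet, SequenceSet, Transcript

__all__ = [
    "CLASS_CODE_PRIORITY",
    "LNCRNA_CODES",
    "FilterAudit",
    "assign_class_codes",
    "filter_lncrna",
    "longest_orf",
    "structural_stats",
]

log = logging.getLogger(__name__)

CLASS_CODE_PRIORITY = ("=", "j", "o", "i", "x", "u")
LNCRNA_CODES = frozenset({"i", "j", "o", "u", "x"})

_STOPS = {"TAA", "TAG", "TGA"}


def _exon_trees(reference: AnnotationSet) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tx in reference:
        tree = trees.setdefault((tx.chrom, tx.strand), IntervalTree())
        for s, e in tx.exons:
            tree[s:e] = tx.transcript_id
    return trees


def assign_class_codes(
    candidates: AnnotationSet, reference: AnnotationSet
) -> dict[str, str]:
    """Assign one class code per candidate by the fixed priority (=, j, o, i, x, u)."""
    by_chrom: dict[str, list[Transcript]] = {}
    chroms = set()
    for tx in reference:
        by_chrom.setdefault(tx.chrom, []).append(tx)
        chroms.add(tx.chrom)
    exon_trees = _exon_trees(reference)
    codes: dict[str, str] = {}
    for cand in candidates:
        if cand.chrom not in chroms:
            log.warning(
                "candidate %s on unannotated chromosome %s; coded 'u'",
                cand.transcript_id,
                cand.chrom,
            )
            codes[cand.transcript_id] = "u"
            continue
        refs = by_chrom[cand.chrom]
        same = [r for r in refs if r.strand == cand.strand]
        code = None
        # "=": identical exon chain
        if any(r.exons == cand.exons for r in same):
            code = "="
        # "j": shares >= 1 intron junction with a same-strand reference
        if code is None and len(cand.exons) > 1:
            cand_introns = set(cand.introns())
            if any(cand_introns & set(r.introns()) for r in same):
                code = "j"
        # "o": any other same-strand exonic overlap
        if code is None:
            tree = exon_trees.get((cand.chrom, cand.strand))
            if tree is not None and any(
                tree.overlap(s, e) for s, e in cand.exons
            ):
                code = "o"
        # "i": fully contained within an intron of a same-strand reference
        if code is None and any(
            intron[0] <= cand.start and cand.end <= intron[1]
            for r in same
            for intron in r.introns()
        ):
            code = "i"
        # "x": exonic overlap on the opposite strand
        if code is None:
            other = "-" if cand.strand == "+" else "+"
            tree = exon_trees.get((cand.chrom, other))
            if tree is not None and any(
                tree.overlap(s, e) for s, e in cand.exons
            ):
                code = "x"
        codes[cand.transcript_id] = code or "u"
    return codes


@dataclass
class FilterAudit:
    """Per-step removal counts of the lncRNA candidate filter (applied in order)."""

    n_input: int = 0
    removed_length: int = 0
    removed_class_code: int = 0
    removed_coding_potential: int = 0
    removed_missing_scores: int = 0
    n_retained: int = 0
    convention: str = "literal"
    notes: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_length", self.removed_length),
            ("removed_class_code", self.removed_class_code),
            ("removed_coding_potential", self.removed_coding_potential),
            ("removed_missing_scores", self.removed_missing_scores),
            ("retained", self.n_retained),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def _deleted_by_coding(cnci: float, cpc: float, convention: str) -> bool:
    if convention == "literal":
        return cnci < 0 and cpc < -1
    if convention == "standard":
        return cnci >= 0 or cpc >= -1
    raise ValueError("convention must be 'literal' or 'standard'")


def filter_lncrna(
    candidates: AnnotationSet,
    codes: dict[str, str],
    coding: pd.DataFrame,
    min_length: int = 200,
    convention: str = "literal",
    missing: str = "drop",
) -> tuple[list[str], FilterAudit]:
    """Filter candidates to lncRNAs; returns (retained ids, audit).

    ``coding`` is a table indexed by transcript_id with columns ``cnci_like``
    and ``cpc_like``. ``missing`` controls transcripts absent from it:
    ``"drop"`` removes them, ``"pass"`` keeps them with a warning. Steps are
    applied in the order length -> class code -> coding potential, and the
    audit records removals per step.
    """
    if missing not in ("drop", "pass"):
        raise ValueError("missing must be 'drop' or 'pass'")
    audit = FilterAudit(n_input=len(candidates), convention=convention)
    audit.notes.append("Pfam-style domain filtering not applied")
    survivors: list[Transcript] = []
    for tx in sorted(candidates, key=lambda t: t.transcript_id):
        if tx.length < min_length:
            audit.removed_length += 1
            continue
        survivors.append(tx)
    retained: list[str] = []
    stage2: list[Transcript] = []
    for tx in survivors:
        if codes.get(tx.transcript_id) not in LNCRNA_CODES:
            audit.removed_class_code += 1
            continue
        stage2.append(tx)
    for tx in stage2:
        tid = tx.transcript_id
        if tid not in coding.index:
            if missing == "drop":
                audit.removed_missing_scores += 1
                continue
            log.warning("no coding-potential scores for %s; passed through", tid)
            retained.append(tid)
            continue
        row = coding.loc[tid]
        if _deleted_by_coding(float(row["cnci_like"]), float(row["cpc_like"]), convention):
            audit.removed_coding_potential += 1
            continue
        retained.append(tid)
    audit.n_retained = len(retained)
    return retained, audit


def longest_orf(sequence: str) -> int:
    """Length in nt (ATG..stop inclusive) of the longest complete forward ORF.

    Only the three forward frames are searched (transcripts are
    strand-resolved); an ATG without an in-frame stop does not count.
    Returns 0 when no complete ORF exists.
    """
    seq = sequence.upper().replace("U", "T")
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def structural_stats(
    lncrna_ids: list[str],
    mrna_ids: list[str],
    annotation: AnnotationSet,
    sequences: SequenceSet,
    length_bins: tuple[int, ...] = (0, 200, 500, 1000, 2000),
    orf_bins: tuple[int, ...] = (0, 100, 300, 500, 1000),
) -> pd.DataFrame:
    """Per-class structural summaries: length bins, ORF-length bins, exon counts.

    Returns a long-format table with columns (rna_class, statistic, bin,
    count), deterministic ordering.
    """
    rows = []
    for cls, ids in (("lncRNA", lncrna_ids), ("mRNA", mrna_ids)):
        lengths, orfs, exon_counts = [], [], []
        for tid in ids:
            tx = annotation[tid]
            lengths.append(tx.length)
            exon_counts.append(len(tx.exons))
            orfs.append(longest_orf(sequences[tid]) if tid in sequences.records else 0)
        for stat, values, bins in (
            ("transcript_length", lengths, length_bins),
            ("orf_length", orfs, orf_bins),
        ):
            edges = list(bins) + [float("inf")]
            for lo, hi in zip(edges, edges[1:]):
                label = f"[{lo},{hi})" if hi != float("inf") else f">={lo}"
                rows.append(
                    (cls, stat, label, sum(1 for v in values if lo <= v < hi))
                )
        for k in sorted(set(exon_counts)):
            rows.append((cls, "exon_count", str(k), exon_counts.count(k)))
    return pd.DataFrame(rows, columns=["rna_class", "statistic", "bin", "count"])
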