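"""Readers and writers for the external formats the pipeline touches.

Conventions enforced here, once, for the whole package:

* internal genomic coordinates are 0-based half-open; the GTF boundary is the
  only place where 1-based inclusive coordinates exist;
* miRNA sequences are stored as RNA (``U``), transcript sequences as DNA
  (``T``); the only normalisation applied is case folding plus a single
  ``T``/``U`` swap;
* all output files are written with deterministic (lexicographic) ordering so
  repeated runs are byte-identical and diffable.

Malformed input is always a hard :class:`FormatError` naming the file and,
where meaningful, the line; nothing is silently coerced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceSet",
    "Transcript",
    "AnnotationSet",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_counts",
    "write_counts",
    "write_network_sif",
    "write_network_graphml",
]

_RNA_OK = set("ACGUN")
_DNA_OK = set("ACGTN")


class FormatError(ValueError):
    """Raised for any malformed external file."""


def _normalize(seq: str, alphabet: str, *, where: str) -> str:
    s = seq.upper()
    if alphabet == "rna":
        s = s.replace("T", "U")
        ok = _RNA_OK
    elif alphabet == "dna":
        s = s.replace("U", "T")
        ok = _DNA_OK
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(s) - ok
    if bad:
        raise FormatError(f"{where}: non-nucleotide character(s) {sorted(bad)}")
    if not s:
        raise FormatError(f"{where}: empty sequence")
    return s


@dataclass
class SequenceSet:
    """Ordered identifier -> nucleotide sequence map with a fixed alphabet."""

    records: dict[str, str] = field(default_factory=dict)
    alphabet: str = "dna"  # "dna" | "rna"

    def add(self, identifier: str, sequence: str) -> None:
        if identifier in self.records:
            raise FormatError(f"duplicate sequence identifier {identifier!r}")
        self.records[identifier] = _normalize(
            sequence, self.alphabet, where=f"record {identifier!r}"
        )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, identifier: str) -> str:
        return self.records[identifier]

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()


def read_fasta(path, alphabet: str = "dna") -> SequenceSet:
    """Load a FASTA file into a :class:`SequenceSet`, order preserved.

    Duplicate headers and non-nucleotide characters are hard errors.
    """
    out = SequenceSet(alphabet=alphabet)
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.add(rec.id, str(rec.seq))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    if len(out) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation (GTF)
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One transcript: sorted, non-overlapping exons in 0-based half-open coords."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class AnnotationSet:
    """Transcript models keyed by transcript_id, plus the derived gene index."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, tx: Transcript) -> None:
        if tx.transcript_id in self.transcripts:
            raise FormatError(f"duplicate transcript_id {tx.transcript_id!r}")
        exons = sorted(tx.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise FormatError(
                    f"transcript {tx.transcript_id!r}: overlapping exons"
                )
        tx.exons = exons
        self.transcripts[tx.transcript_id] = tx

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> Transcript:
        return self.transcripts[tid]

    def genes(self) -> dict[str, tuple[str, str, int, int]]:
        """gene_id -> (chrom, strand, span start, span end) over its transcripts."""
        out: dict[str, tuple[str, str, int, int]] = {}
        for tx in self:
            if tx.gene_id in out:
                c, st, s, e = out[tx.gene_id]
                out[tx.gene_id] = (c, st, min(s, tx.start), max(e, tx.end))
            else:
                out[tx.gene_id] = (tx.chrom, tx.strand, tx.start, tx.end)
        return out


def _parse_gtf_attrs(text: str, where: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise FormatError(f"{where}: malformed attribute {chunk!r}") from None
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> AnnotationSet:
    """Read exon features from a GTF file.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open
    here and nowhere else. Exons are stored sorted per transcript.
    """
    pending: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            where = f"{path}:{lineno}"
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{where}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{where}: non-integer coordinates") from None
            if end_i < start_i:
                raise FormatError(f"{where}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{where}: unknown strand {strand!r}")
            attrs = _parse_gtf_attrs(attr, where)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise FormatError(f"{where}: missing {key} attribute")
            tid = attrs["transcript_id"]
            exon = (start_i - 1, end_i)  # to 0-based half-open
            if tid in pending:
                tx = pending[tid]
                if tx.chrom != chrom or tx.strand != strand:
                    raise FormatError(
                        f"{where}: transcript {tid!r} spans chrom/strand"
                    )
                tx.exons.append(exon)
            else:
                pending[tid] = Transcript(tid, attrs["gene_id"], chrom, strand, [exon])
    out = AnnotationSet()
    for tid in pending:
        out.add(pending[tid])
    return out


def write_gtf(annotation: AnnotationSet, path, source: str = "cerna_forge") -> None:
    """Write exon records, 1-based inclusive, ordered by (chrom, start, id)."""
    txs = sorted(
        annotation, key=lambda t: (t.chrom, t.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for tx in txs:
            for s, e in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Feature x library integer counts, with optional feature lengths in bp."""

    counts: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise FormatError("count table contains negative values")
        if not all(
            pd.api.types.is_integer_dtype(t) for t in self.counts.dtypes
        ):
            raise FormatError("count table must be integer-valued")
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise FormatError(f"library totals must be > 0 (violated by {bad})")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


def read_counts(path, lengths_path=None) -> CountTable:
    """Read a TSV count table: first column feature_id, remaining columns libraries."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature identifiers {dups[:5]}")
    try:
        df = df.astype("int64")
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer counts") from None
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0, comment="#")
        lengths = ldf.iloc[:, 0]
    return CountTable(df, lengths)


def write_counts(table: CountTable, path) -> None:
    table.counts.sort_index().to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def _check_node_id(name: str) -> str:
    if "\t" in name or "\n" in name or "\r" in name:
        raise FormatError(f"node identifier {name!r} contains tab/newline")
    return name


def write_network_sif(edges, path) -> None:
    """Write (source, relation, target) triples as SIF, lexicographically sorted.

    ``edges`` is an iterable of 3-tuples; the relation field carries the edge
    type (e.g. ``miRNA-mRNA``). Output is byte-deterministic.
    """
    lines = sorted(
        (
            _check_node_id(str(s)),
            _check_node_id(str(r)),
            _check_node_id(str(t)),
        )
        for s, r, t in edges
    )
    with open(path, "w") as fh:
        for s, r, t in lines:
            fh.write(f"{s}\t{r}\t{t}\n")


def write_network_graphml(edges, path, node_attrs: dict[str, dict] | None = None) -> None:
    """Write a typed directed network as GraphML (deterministic node/edge order)."""
    g = nx.DiGraph()
    sorted_edges = sorted(
        (
            _check_node_id(str(s)),
            _check_node_id(str(r)),
            _check_node_id(str(t)),
        )
        for s, r, t in edges
    )
    nodes = sorted({s for s, _, t in sorted_edges} | {t for s, _, t in sorted_edges})
    if node_attrs:
        nodes = sorted(set(nodes) | set(node_attrs))
    for n in nodes:
        g.add_node(n, **(node_attrs.get(n, {}) if node_attrs else {}))
    for s, r, t in sorted_edges:
        g.add_edge(s, t, relation=r)
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def read_network_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(str(path))
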