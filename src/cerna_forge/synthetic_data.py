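"""Synthetic scenarios with planted ground truth for every pipeline stage.

The generator emulates the two-library anther/vegetative study design:
random transcript backgrounds with planted miRNA target duplexes of known
penalty, planted sponge sites that satisfy or violate the matching rules,
two-library count matrices with planted log2 fold changes, back-splice
junction read evidence with controlled mismatches and spans, and genomic
placements of lncRNAs at controlled distances from coding genes.

Every planted structure is verified against the analysis code before
emission (a planted duplex is re-aligned and must score exactly as
requested; a planted sponge violator must not be rescued by an alternative
compliant path), and decoy background is resampled until it contains no
accidental sites. Truth tables are emitted alongside the data so the
expected result of each stage is analytically enumerable. The same seed
always yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circrna_caller import JunctionEvidence
from .io_formats import AnnotationSet, SequenceSet, Transcript, write_fasta, write_gtf
from .sponge_matcher import SpongeRuleSet, match_sponge_sites
from .target_scoring import (
    GU,
    MISMATCH,
    TARGET_BULGE,
    ScoringScheme,
    _scan_min_scores,
    align_site,
    predict_targets,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "plant_duplex",
    "compose_penalty",
    "make_penalty_ladder",
    "make_cis_ladder",
    "make_scenario",
]

_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    codes = rng.integers(0, len(alphabet), size=n)
    return np.frombuffer(
        np.array([ord(c) for c in alphabet], dtype=np.uint8)[codes].tobytes(), dtype="S1"
    ).tobytes().decode()


def _mismatch_choice(rng: np.random.Generator, mirna_nt: str) -> str:
    comp = _RNA_COMP[mirna_nt]
    wobble = {"G": "U", "U": "G"}.get(mirna_nt)
    options = [c for c in "ACGU" if c != comp and c != wobble]
    return options[int(rng.integers(0, len(options)))]


def expected_penalty(
    mirna: str, composition: dict, scheme: ScoringScheme | None = None
) -> float:
    """Penalty a planted composition should score under the scheme."""
    scheme = scheme or ScoringScheme()
    m = len(mirna)
    total = 0.0
    for p in composition.get("gu", ()):
        total += scheme.penalty(GU, p)
    for p in composition.get("mismatch", ()):
        total += scheme.penalty(MISMATCH, p)
    for p, size in composition.get("bulge", ()):
        total += size * scheme.penalty(TARGET_BULGE, min(p + 1, m))
    return total


def plant_duplex(
    mirna: str,
    composition: dict,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
    max_tries: int = 50,
) -> tuple[str, float]:
    """Construct a target window whose optimal alignment realises ``composition``.

    ``composition`` holds 1-based miRNA positions: ``{"gu": [...],
    "mismatch": [...], "bulge": [(after_pos, size), ...]}``; unlisted
    positions pair Watson-Crick. The window is returned 5'->3' in RNA
    alphabet together with its verified penalty. The construction is
    re-randomised until :func:`align_site` confirms the optimal path scores
    exactly the expected penalty (guards against accidental better
    alignments through repeats); infeasible compositions raise.
    """
    scheme = scheme or ScoringScheme()
    m = len(mirna)
    gu = set(composition.get("gu", ()))
    mm = set(composition.get("mismatch", ()))
    bulges = dict(composition.get("bulge", ()))
    if gu & mm:
        raise ValueError("a position cannot be both G:U and mismatch")
    for p in gu | mm | set(bulges):
        if not (1 <= p <= m):
            raise ValueError(f"position {p} outside miRNA 1..{m}")
    for p in gu:
        if mirna[p - 1] not in "GU":
            raise ValueError(
                f"G:U wobble infeasible at position {p} (miRNA nt {mirna[p-1]})"
            )
    want = expected_penalty(mirna, composition, scheme)
    for _ in range(max_tries):
        path_nts: list[str] = []
        for p in range(1, m + 1):
            nt = mirna[p - 1]
            if p in gu:
                path_nts.append("U" if nt == "G" else "G")
            elif p in mm:
                path_nts.append(_mismatch_choice(rng, nt))
            else:
                path_nts.append(_RNA_COMP[nt])
            if p in bulges:
                path_nts.extend(
                    _random_seq(rng, bulges[p], "ACGU")
                )
        window = "".join(reversed(path_nts))
        aln = align_site(mirna, window, scheme, max_gaps=2)
        if abs(aln.score - want) < 1e-9:
            return window, want
    raise RuntimeError(
        f"could not realise composition {composition} at penalty {want} "
        f"after {max_tries} tries"
    )


def compose_penalty(
    mirna: str,
    score: float,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
) -> dict:
    """Choose a random position composition realising ``score`` exactly.

    Works in half-point units with the default scheme geometry: non-core
    G:U = 0.5, core G:U and non-core mismatch = 1, core mismatch = 2.
    Requires the miRNA to offer a G/U nucleotide where a wobble is needed.
    """
    scheme = scheme or ScoringScheme()
    m = len(mirna)
    units = int(round(score * 2))
    if abs(units - score * 2) > 1e-9 or units < 0:
        raise ValueError(f"penalty {score} is not a multiple of 0.5")
    core = [p for p in range(1, m + 1) if scheme.in_core(p)]
    noncore = [p for p in range(1, m + 1) if not scheme.in_core(p)]
    gu_core = [p for p in core if mirna[p - 1] in "GU"]
    gu_noncore = [p for p in noncore if mirna[p - 1] in "GU"]
    rng.shuffle(core)
    rng.shuffle(noncore)
    rng.shuffle(gu_core)
    rng.shuffle(gu_noncore)
    used: set[int] = set()

    def take(pool: list[int]) -> int | None:
        while pool:
            p = pool.pop()
            if p not in used:
                used.add(p)
                return p
        return None

    comp: dict[str, list] = {"gu": [], "mismatch": [], "bulge": []}
    if units % 2 == 1:
        p = take(gu_noncore)
        if p is None:
            raise ValueError("no non-core G/U position free for a 0.5 penalty")
        comp["gu"].append(p)
        units -= 1
    pairs = units // 2
    while pairs > 0:
        if pairs >= 2:
            p = take(core)
            if p is not None:
                comp["mismatch"].append(p)
                pairs -= 2
                continue
        p = take(noncore)
        if p is not None:
            comp["mismatch"].append(p)
            pairs -= 1
            continue
        p = take(gu_core)
        if p is not None:
            comp["gu"].append(p)
            pairs -= 1
            continue
        raise ValueError(f"cannot realise remaining {pairs} penalty points")
    return comp


def make_penalty_ladder(
    penalties: list[float],
    seed: int = 0,
    scheme: ScoringScheme | None = None,
    mirna_length: int = 21,
    transcript_length: int = 150,
) -> tuple[SequenceSet, SequenceSet, pd.DataFrame]:
    """One miRNA and one transcript per requested penalty, planted and verified.

    Returns (miRNA set, transcript set, truth table with the verified
    penalty and window of each planted site). Backgrounds are resampled
    until no accidental site at or below the retention cutoff exists.
    """
    scheme = scheme or ScoringScheme()
    rng = np.random.default_rng(seed)
    mir = _random_seq(rng, mirna_length, "ACGU")
    while not any(c in "GU" for c in mir):  # pragma: no cover - virtually sure
        mir = _random_seq(rng, mirna_length, "ACGU")
    mirnas = SequenceSet(alphabet="rna")
    mirnas.add("miR_L1", mir)
    transcripts = SequenceSet(alphabet="dna")
    rows = []
    for idx, pen in enumerate(penalties, start=1):
        comp = compose_penalty(mir, pen, rng, scheme)
        window, verified = plant_duplex(mir, comp, rng, scheme)
        tid = f"tx_{idx:03d}"
        seq, start = _splice_site(rng, window, transcript_length, mir, scheme)
        transcripts.add(tid, seq)
        rows.append(
            {
                "mirna_id": "miR_L1",
                "target_id": tid,
                "start": start,
                "end": start + len(window),
                "penalty": verified,
            }
        )
    truth = pd.DataFrame(rows)
    return mirnas, transcripts, truth


def _splice_site(
    rng: np.random.Generator,
    window_rna: str,
    length: int,
    mirna: str,
    scheme: ScoringScheme,
    max_tries: int = 50,
) -> tuple[str, int]:
    """Embed one window in random background free of accidental sites.

    The background is resampled until the only windows scoring at or below
    the retention cutoff (+0.5 safety margin) overlap the planted one.
    Returns (DNA sequence, planted start).
    """
    wlen = len(window_rna)
    window_dna = window_rna.replace("U", "T")
    for _ in range(max_tries):
        start = int(rng.integers(5, length - wlen - 5))
        seq = (
            _random_seq(rng, start)
            + window_dna
            + _random_seq(rng, length - start - wlen)
        )
        scores = _scan_min_scores(mirna, seq, scheme, max_gaps=2)
        bad = False
        for j in np.nonzero(scores <= scheme.max_score + 0.5)[0]:
            # any admissible window ending at j overlaps [j-23, j)
            if j <= start or j - 23 >= start + wlen:
                bad = True
                break
        if not bad:
            return seq, start
    raise RuntimeError("could not embed site without accidental background hits")


def _clean_background(
    rng: np.random.Generator,
    length: int,
    mirnas: SequenceSet,
    scheme: ScoringScheme,
    max_tries: int = 50,
) -> str:
    """Random DNA with no window at or below the cutoff for any miRNA."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        ok = True
        for _, mir in mirnas.items():
            if (_scan_min_scores(mir, seq, scheme, 2) <= scheme.max_score + 0.5).any():
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("could not generate clean background")


def make_cis_ladder(
    gaps: tuple[int, ...] = (25_000, 50_000, 100_000, 150_000),
    transcript_length: int = 1_000,
) -> tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
    """Isolated (gene, lncRNA) pairs at controlled genomic gaps.

    Each pair sits on its own chromosome, the lncRNA exactly ``gap`` bp
    downstream of the gene end. Returns (lncRNA annotation, gene annotation,
    truth table with the planted gap per pair).
    """
    lncs, genes = AnnotationSet(), AnnotationSet()
    rows = []
    for i, gap in enumerate(gaps, start=1):
        chrom = f"chrL{i}"
        gstart = 10_000
        gend = gstart + transcript_length
        genes.add(
            Transcript(f"GENE_cis{i}", f"GENE_cis{i}", chrom, "+", [(gstart, gend)])
        )
        ls = gend + gap
        lncs.add(
            Transcript(
                f"LNC_cis{i}", f"LNC_cis{i}", chrom, "+", [(ls, ls + transcript_length)]
            )
        )
        rows.append({"lncrna_id": f"LNC_cis{i}", "mrna_id": f"GENE_cis{i}", "gap": gap})
    return lncs, genes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a full planted scenario.

    Defaults mirror the study design at desk scale: two libraries ('Mix'
    vegetative reference, 'Ant' anther), 21-nt miRNAs, a minority of
    features differentially expressed at |log2FC| = 3, Poisson counts
    (``dispersion`` = 0) at moderate depth, back-splice evidence straddling
    every filter boundary, and lncRNA placements at the cis-window ladder.
    """

    seed: int = 0
    n_mirnas: int = 30
    mirna_length: int = 21
    n_mrnas: int = 200
    mrna_length: int = 300
    n_lncrnas: int = 20
    lncrna_length: int = 300
    n_circrnas: int = 10
    circrna_length: int = 150
    n_chromosomes: int = 3
    target_site_fraction: float = 0.25
    target_penalties: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0
    )
    sponge_fraction: float = 0.6
    violator_fraction: float = 0.3
    frac_de: float = 0.3
    planted_lfc: float = 3.0
    dispersion: float = 0.0
    base_mean_range: tuple[float, float] = (200.0, 2000.0)
    n_specific: int = 2
    cis_gaps: tuple[int, ...] = (25_000, 50_000, 100_000, 150_000)
    junction_spans: tuple[int, ...] = (5_000, 20_000, 99_999, 150_000)


@dataclass
class Scenario:
    """In-memory result of :func:`make_scenario` plus its truth tables."""

    config: ScenarioConfig
    mirnas: SequenceSet
    mrna_seqs: SequenceSet
    ncrna_seqs: SequenceSet
    ncrna_classes: dict[str, str]
    reference: AnnotationSet
    candidates: AnnotationSet
    counts: "pd.DataFrame"
    lengths: pd.Series
    class_map: dict[str, str]
    coding: pd.DataFrame
    junction_evidence: list[JunctionEvidence]
    truth_target_sites: pd.DataFrame
    truth_sponge_sites: pd.DataFrame
    truth_de: pd.DataFrame
    truth_junctions: pd.DataFrame
    truth_cis: pd.DataFrame
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Write every pipeline input plus truth tables to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.mirnas, out / "mirnas.fasta")
        write_fasta(self.mrna_seqs, out / "mrnas.fasta")
        write_fasta(self.ncrna_seqs, out / "ncrnas.fasta")
        write_gtf(self.reference, out / "reference.gtf")
        write_gtf(self.candidates, out / "candidates.gtf")
        counts = self.counts.sort_index()
        counts.to_csv(out / "counts.tsv", sep="\t", index_label="feature_id")
        self.lengths.sort_index().to_frame("length").to_csv(
            out / "lengths.tsv", sep="\t", index_label="feature_id"
        )
        pd.Series(self.class_map, name="rna_class").sort_index().to_csv(
            out / "class_map.tsv", sep="\t", index_label="feature_id"
        )
        self.coding.sort_index().to_csv(
            out / "coding_potential.tsv", sep="\t", index_label="transcript_id"
        )
        pd.DataFrame(
            [
                {
                    "read_id": e.read_id,
                    "chrom": e.chrom,
                    "strand": e.strand,
                    "acceptor": e.acceptor,
                    "donor": e.donor,
                    "mismatches": e.mismatches,
                }
                for e in self.junction_evidence
            ]
        ).to_csv(out / "junctions.tsv", sep="\t", index=False)
        rng = np.random.default_rng(self.config.seed + 7)
        with open(out / "genome.fasta", "w") as fh:
            for chrom in sorted(self.genome_lengths):
                fh.write(f">{chrom}\n")
                seq = _random_seq(rng, self.genome_lengths[chrom])
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        for name in (
            "truth_target_sites",
            "truth_sponge_sites",
            "truth_de",
            "truth_junctions",
            "truth_cis",
        ):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest = {"seed": self.config.seed, "config": asdict(self.config)}
        with open(out / "scenario.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _make_mirnas(rng, cfg) -> SequenceSet:
    out = SequenceSet(alphabet="rna")
    scheme = ScoringScheme()

    def plantable(seq: str) -> bool:
        noncore_gu = sum(
            c in "GU" for p, c in enumerate(seq, start=1) if not scheme.in_core(p)
        )
        return noncore_gu >= 2 and sum(c in "GU" for c in seq) >= 4

    for i in range(1, cfg.n_mirnas + 1):
        seq = _random_seq(rng, cfg.mirna_length, "ACGU")
        while not plantable(seq):  # keep wobbles plantable anywhere needed
            seq = _random_seq(rng, cfg.mirna_length, "ACGU")
        out.add(f"miR_{i:03d}", seq)
    return out


def _plant_target_sites(rng, cfg, mirnas, scheme):
    """mRNA sequences with planted duplexes; returns (seqs, truth rows)."""
    seqs = SequenceSet(alphabet="dna")
    rows = []
    mir_ids = list(mirnas)
    n_planted = int(round(cfg.n_mrnas * cfg.target_site_fraction))
    for i in range(1, cfg.n_mrnas + 1):
        tid = f"mRNA_{i:04d}"
        if i <= n_planted:
            mirna_id = mir_ids[(i - 1) % len(mir_ids)]
            mir = mirnas[mirna_id]
            pen = cfg.target_penalties[(i - 1) % len(cfg.target_penalties)]
            seq, start, wlen = _plant_verified_target(
                rng, cfg, mirnas, mirna_id, pen, scheme
            )
            seqs.add(tid, seq)
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "target_id": tid,
                    "start": start,
                    "end": start + wlen,
                    "penalty": pen,
                }
            )
        else:
            seqs.add(tid, _clean_background(rng, cfg.mrna_length, mirnas, scheme))
    return seqs, pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "start", "end", "penalty"]
    )


def _plant_verified_target(rng, cfg, mirnas, mirna_id, pen, scheme):
    """Embed one planted duplex and verify it end to end with the predictor.

    The embedded transcript must (a) yield, for the planted miRNA, exactly
    the planted window at exactly the requested penalty when the penalty is
    retainable — or no site at all for decoy penalties above the cutoff
    (overlapping sub-windows can otherwise realign more cheaply); and
    (b) contain no site at or below the cutoff for any other miRNA.
    """
    mir = mirnas[mirna_id]
    mir_ids = list(mirnas)
    single = SequenceSet(alphabet="rna")
    single.add(mirna_id, mir)
    for _ in range(60):
        try:
            comp = compose_penalty(mir, pen, rng, scheme)
            window, _ = plant_duplex(mir, comp, rng, scheme)
        except (ValueError, RuntimeError):
            continue
        seq, start = _splice_site(rng, window, cfg.mrna_length, mir, scheme)
        tmp = SequenceSet(alphabet="dna")
        tmp.add("tx", seq)
        preds = predict_targets(single, tmp, scheme)
        got = [(p.target_window[0], p.target_window[1], p.score) for p in preds]
        want = (
            [(start, start + len(window), pen)]
            if pen <= scheme.max_score + 1e-9
            else []
        )
        if got != want:
            continue
        if any(
            (
                _scan_min_scores(mirnas[m2], seq, scheme, 2) <= scheme.max_score + 0.5
            ).any()
            for m2 in mir_ids
            if m2 != mirna_id
        ):
            continue
        return seq, start, len(window)
    raise RuntimeError(
        f"could not plant a verified {pen}-point site for {mirna_id}"
    )


def _sponge_window(rng, mir, kind: str, rules: SpongeRuleSet) -> tuple[str, bool]:
    """Build a sponge window of a planted kind; returns (window RNA, compliant)."""
    m = len(mir)
    outside = [
        p for p in range(1, m + 1) if not rules.in_middle(p)
    ]

    def spread(k: int) -> list[int]:
        pool = outside[:]
        rng.shuffle(pool)
        chosen: list[int] = []
        for p in pool:
            if all(abs(p - q) > 2 for q in chosen):
                chosen.append(p)
            if len(chosen) == k:
                break
        return chosen

    path_nts: list[str] = []
    if kind == "perfect":
        mism, bulge = [], None
    elif kind == "mismatch2":
        mism, bulge = spread(2), None
    elif kind == "mismatch4":
        mism, bulge = spread(4), None
    elif kind == "middle_bulge":
        mism, bulge = [], (int(rng.integers(rules.middle_start, rules.middle_end)), 1)
    elif kind == "violator_mismatch5":
        mism, bulge = spread(5), None
    elif kind == "violator_run3":
        p0 = int(rng.integers(2, rules.middle_start - 3))
        mism, bulge = [p0, p0 + 1, p0 + 2], None
    else:
        raise ValueError(f"unknown sponge kind {kind!r}")
    for p in range(1, m + 1):
        if p in mism:
            path_nts.append(_mismatch_choice(rng, mir[p - 1]))
        else:
            path_nts.append(_RNA_COMP[mir[p - 1]])
        if bulge and p == bulge[0]:
            path_nts.extend(_random_seq(rng, bulge[1], "ACGU"))
    compliant = not kind.startswith("violator")
    return "".join(reversed(path_nts)), compliant


def _plant_sponges(rng, cfg, mirnas, rules, scheme):
    """ncRNA sequences (lncRNA + circRNA) with planted sponge sites."""
    seqs = SequenceSet(alphabet="dna")
    classes: dict[str, str] = {}
    rows = []
    mir_ids = list(mirnas)
    kinds = ["perfect", "mismatch2", "mismatch4", "middle_bulge"]
    violator_kinds = ["violator_mismatch5", "violator_run3"]
    specs = []
    for i in range(1, cfg.n_lncrnas + 1):
        specs.append((f"LNC_{i:04d}", "lncRNA", cfg.lncrna_length))
    for i in range(1, cfg.n_circrnas + 1):
        specs.append((f"circ_{i:04d}", "circRNA", cfg.circrna_length))
    n_sponge = 0
    n_viol = 0
    for idx, (nid, ncls, length) in enumerate(specs):
        classes[nid] = ncls
        u = rng.random()
        if u < cfg.sponge_fraction:
            kind = kinds[n_sponge % len(kinds)]
            n_sponge += 1
        elif u < cfg.sponge_fraction + cfg.violator_fraction:
            kind = violator_kinds[n_viol % len(violator_kinds)]
            n_viol += 1
        else:
            kind = None
        mirna_id = mir_ids[idx % len(mir_ids)]
        mir = mirnas[mirna_id]
        for attempt in range(60):
            if kind is None:
                seq = _random_seq(rng, length)
                candidate_truth = None
            else:
                window, compliant = _sponge_window(rng, mir, kind, rules)
                wdna = window.replace("U", "T")
                wrap = ncls == "circRNA" and kind == "perfect" and attempt < 30
                if wrap:
                    cut = len(wdna) // 2
                    start = length - cut
                    body = _random_seq(rng, length - len(wdna))
                    seq = wdna[cut:] + body + wdna[:cut]
                else:
                    start = int(rng.integers(2, length - len(wdna) - 2))
                    seq = (
                        _random_seq(rng, start)
                        + wdna
                        + _random_seq(rng, length - start - len(wdna))
                    )
                end = (start + len(wdna)) % length if wrap else start + len(wdna)
                candidate_truth = {
                    "mirna_id": mirna_id,
                    "ncrna_id": nid,
                    "ncrna_class": ncls,
                    "start": start,
                    "end": end,
                    "kind": kind,
                    "compliant": compliant,
                }
            tmp = SequenceSet(alphabet="dna")
            tmp.add(nid, seq)
            hits = match_sponge_sites(mirnas, tmp, rules, {nid: ncls})
            got = {(h.mirna_id, h.window[0], h.window[1]) for h in hits}
            if candidate_truth is not None and candidate_truth["compliant"]:
                planted_key = (mirna_id, candidate_truth["start"], candidate_truth["end"])
                # the planted site must survive scanning and overlap-merging
                if planted_key not in got:
                    continue
            if candidate_truth is not None and not candidate_truth["compliant"]:
                # a violator window's unique 1:1 path breaks a rule by
                # construction, so its exact window can never be reported
                viol_key = (mirna_id, candidate_truth["start"], candidate_truth["end"])
                if viol_key in got:  # pragma: no cover - structurally impossible
                    continue
            seqs.add(nid, seq)
            if candidate_truth is not None:
                rows.append(candidate_truth)
            planted_keys = (
                {(mirna_id, candidate_truth["start"], candidate_truth["end"])}
                if candidate_truth is not None and candidate_truth["compliant"]
                else set()
            )
            # rule-compliant windows also arise by chance in realistic-length
            # background; record them so stage truth stays enumerable
            for h in hits:
                key = (h.mirna_id, h.window[0], h.window[1])
                if key in planted_keys:
                    continue
                rows.append(
                    {
                        "mirna_id": h.mirna_id,
                        "ncrna_id": nid,
                        "ncrna_class": ncls,
                        "start": h.window[0],
                        "end": h.window[1],
                        "kind": "incidental",
                        "compliant": True,
                    }
                )
            break
        else:
            raise RuntimeError(f"could not plant sponge scenario for {nid}")
    truth = pd.DataFrame(
        rows,
        columns=["mirna_id", "ncrna_id", "ncrna_class", "start", "end", "kind", "compliant"],
    )
    return seqs, classes, truth


def _layout_genome(rng, cfg, mrna_ids, lnc_ids):
    """Place mRNA genes and lncRNA candidates; returns annotations and truths."""
    reference = AnnotationSet()
    candidates = AnnotationSet()
    chrom_cursor = {f"chr{c}": 10_000 for c in range(1, cfg.n_chromosomes + 1)}
    chroms = sorted(chrom_cursor)
    placements: dict[str, tuple[str, int, int]] = {}
    lnc_iter = iter(lnc_ids)
    gap_cycle = list(cfg.cis_gaps)
    for i, tid in enumerate(mrna_ids):
        chrom = chroms[i % len(chroms)]
        pos = chrom_cursor[chrom]
        n_exons = int(rng.integers(1, 5))
        exon_lens = _partition(rng, cfg.mrna_length, n_exons)
        exons = []
        cur = pos
        for k, el in enumerate(exon_lens):
            exons.append((cur, cur + el))
            cur += el
            if k < n_exons - 1:
                cur += int(rng.integers(100, 800))
        gid = tid.replace("mRNA", "GENE")
        reference.add(Transcript(tid, gid, chrom, "+" if i % 2 == 0 else "-", exons))
        placements[gid] = (chrom, pos, cur)
        chrom_cursor[chrom] = cur + int(rng.integers(3_000, 6_000))
        # every 10th gene gets the next lncRNA planted downstream at a
        # controlled gap from the cis ladder
        if i % 10 == 5:
            lid = next(lnc_iter, None)
            if lid is not None:
                gap = gap_cycle[(i // 10) % len(gap_cycle)]
                ls = cur + gap
                le = ls + cfg.lncrna_length
                candidates.add(
                    Transcript(lid, lid, chrom, "+", [(ls, le)])
                )
                placements[lid] = (chrom, ls, le)
                chrom_cursor[chrom] = le + int(rng.integers(3_000, 6_000))
    # any lncRNAs left over go intergenic, far from everything
    for lid in lnc_iter:
        chrom = chroms[0]
        ls = chrom_cursor[chrom] + 200_000
        le = ls + cfg.lncrna_length
        candidates.add(Transcript(lid, lid, chrom, "+", [(ls, le)]))
        placements[lid] = (chrom, ls, le)
        chrom_cursor[chrom] = le + 5_000
    return reference, candidates, placements, chrom_cursor


def _partition(rng, total: int, parts: int) -> list[int]:
    if parts == 1:
        return [total]
    cuts = sorted(rng.choice(np.arange(50, total - 50), size=parts - 1, replace=False))
    bounds = [0] + [int(c) for c in cuts] + [total]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _filter_decoys(rng, cfg, reference, candidates, coding_rows):
    """Add lncRNA-filter decoys: short, exact-reference-copy, coding-like."""
    ref_txs = sorted(reference, key=lambda t: t.transcript_id)
    chrom = ref_txs[0].chrom
    far = max(t.end for t in reference if t.chrom == chrom) + 500_000
    for i in range(1, 4):
        tid = f"SHORT_{i:02d}"
        s = far + i * 10_000
        candidates.add(Transcript(tid, tid, chrom, "+", [(s, s + 150)]))
        coding_rows.append((tid, -3.0, -2.0))
    for i in range(1, 4):
        src = ref_txs[i]
        tid = f"EQ_{i:02d}"
        candidates.add(
            Transcript(tid, tid, src.chrom, src.strand, list(src.exons))
        )
        coding_rows.append((tid, -3.0, -2.0))
    for i in range(1, 4):
        tid = f"CODY_{i:02d}"
        s = far + 100_000 + i * 10_000
        candidates.add(Transcript(tid, tid, chrom, "+", [(s, s + 400)]))
        coding_rows.append((tid, float(rng.uniform(1, 5)), float(rng.uniform(0, 3))))


def _plant_counts(rng, cfg, features: dict[str, str]):
    """Two-library counts with planted log2 fold changes; returns (df, truth)."""
    lo, hi = cfg.base_mean_range
    fids = list(features)
    n = len(fids)
    de_flags: dict[str, float] = {}
    for cls in ("mRNA", "miRNA", "lncRNA", "circRNA"):
        cls_ids = [f for f in fids if features[f] == cls]
        k = int(round(len(cls_ids) * cfg.frac_de))
        chosen = list(rng.choice(cls_ids, size=k, replace=False)) if k else []
        for j, f in enumerate(sorted(chosen)):
            de_flags[f] = cfg.planted_lfc if j % 2 == 0 else -cfg.planted_lfc
    non_de = [f for f in fids if f not in de_flags]
    specific = sorted(non_de)[: cfg.n_specific]
    # planted fold changes are defined on the depth-normalized scale; the
    # up- and down-regulated mass is balanced exactly (down-regulated
    # features get a proportionally higher baseline) so expected library
    # totals are equal and normalization does not shift null features
    mu_a_map = {f: float(rng.uniform(lo, hi)) for f in fids}
    for f in specific:
        mu_a_map[f] = 0.0
    gained = sum(
        mu_a_map[f] * (2.0 ** lfc - 1.0) for f, lfc in de_flags.items() if lfc > 0
    ) + 800.0 * len(specific)
    lost_unit = sum(
        mu_a_map[f] * (1.0 - 2.0 ** lfc) for f, lfc in de_flags.items() if lfc < 0
    )
    if lost_unit > 0:
        k = gained / lost_unit
        for f, lfc in de_flags.items():
            if lfc < 0:
                mu_a_map[f] *= k
    rows = []
    counts = {}
    for f in fids:
        mu_a = mu_a_map[f]
        lfc = de_flags.get(f, 0.0)
        mu_b = 800.0 if f in specific else mu_a * 2.0 ** lfc
        if f in specific:
            a = 0
            b = int(rng.poisson(mu_b)) + 1
            lfc_truth = np.nan
            spec = "B_only"
        else:
            if cfg.dispersion > 0:
                r = 1.0 / cfg.dispersion
                a = int(rng.negative_binomial(r, r / (r + mu_a)))
                b = int(rng.negative_binomial(r, r / (r + mu_b)))
            else:
                a = int(rng.poisson(mu_a))
                b = int(rng.poisson(mu_b))
            lfc_truth = lfc
            spec = "none"
        counts[f] = (a, b)
        rows.append(
            {
                "feature_id": f,
                "rna_class": features[f],
                "planted_lfc": lfc_truth,
                "is_de": f in de_flags or f in specific,
                "specific": spec,
            }
        )
    df = pd.DataFrame(
        {"Mix": {f: counts[f][0] for f in fids}, "Ant": {f: counts[f][1] for f in fids}},
        dtype="int64",
    )[["Mix", "Ant"]]
    truth = pd.DataFrame(rows)
    return df, truth


def _plant_junctions(rng, cfg, reference, chrom_cursor):
    """Back-splice evidence straddling every filter boundary; returns (reads, truth)."""
    evidence: list[JunctionEvidence] = []
    truth_rows = []
    read_n = 0

    def add(chrom, strand, acc, don, mms, label, circ_type):
        nonlocal read_n
        for mm in mms:
            read_n += 1
            evidence.append(
                JunctionEvidence(f"read_{read_n:05d}", chrom, strand, acc, don, mm)
            )
        surv = sum(1 for mm in mms if mm <= 2)
        truth_rows.append(
            {
                "chrom": chrom,
                "strand": strand,
                "start": acc,
                "end": don,
                "span": don - acc,
                "n_reads": len(mms),
                "surviving_reads": surv,
                "passes": surv >= 1 and (don - acc) < 100_000,
                "circ_type": circ_type,
                "label": label,
            }
        )

    multi = [t for t in reference if len(t.exons) >= 3][: cfg.n_circrnas]
    for k, tx in enumerate(multi):
        acc = tx.exons[0][0] if k % 2 == 0 else tx.exons[1][0]
        don = tx.exons[-1][1] if k % 2 == 0 else tx.exons[-2][1]
        mms = [int(m) for m in rng.integers(0, 3, size=int(rng.integers(1, 5)))]
        add(tx.chrom, tx.strand, acc, don, mms, "exonic", "full_exon")
    if multi:
        tx = multi[0]
        add(
            tx.chrom,
            tx.strand,
            tx.exons[0][0] + 7,
            tx.exons[-1][1] - 3,
            [0, 1],
            "offset",
            "exon_intron",
        )
    chrom = sorted(chrom_cursor)[0]
    base = chrom_cursor[chrom] + 1_000_000
    for i, span in enumerate(cfg.junction_spans):
        add(chrom, "+", base + i * 400_000, base + i * 400_000 + span,
            [0, 1, 2], f"span_{span}", "intergenic")
    # mismatch ladder: junctions whose reads carry 0..4 mismatches
    for mm in range(5):
        acc = base + 3_000_000 + mm * 50_000
        add(chrom, "+", acc, acc + 2_000, [mm], f"mm_{mm}", "intergenic")
    # single- and zero-survivor junctions
    acc = base + 4_000_000
    add(chrom, "+", acc, acc + 3_000, [1], "single_read", "intergenic")
    add(chrom, "+", acc + 100_000, acc + 103_000, [3, 4], "no_survivor", "intergenic")
    order = np.argsort(rng.random(len(evidence)))
    evidence = [evidence[i] for i in order]  # shuffle: callers must not care
    return evidence, pd.DataFrame(truth_rows)


def _naive_cis_truth(placements, de_lnc, de_gene, window=100_000):
    rows = []
    for lid in sorted(de_lnc):
        if lid not in placements:
            continue
        lc, ls, le = placements[lid]
        for gid in sorted(de_gene):
            if gid not in placements:
                continue
            gc, gs, ge = placements[gid]
            if gc != lc:
                continue
            gap = max(gs - le, ls - ge, 0)
            if gap <= window:
                rows.append({"lncrna_id": lid, "mrna_id": gid, "gap": gap})
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "gap"])


def make_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate a complete planted scenario (see :class:`ScenarioConfig`)."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    scheme = ScoringScheme()
    rules = SpongeRuleSet()
    mirnas = _make_mirnas(rng, cfg)
    mrna_seqs, truth_targets = _plant_target_sites(rng, cfg, mirnas, scheme)
    ncrna_seqs, ncrna_classes, truth_sponges = _plant_sponges(
        rng, cfg, mirnas, rules, scheme
    )
    mrna_ids = list(mrna_seqs)
    lnc_ids = [n for n, c in ncrna_classes.items() if c == "lncRNA"]
    reference, candidates, placements, chrom_cursor = _layout_genome(
        rng, cfg, mrna_ids, lnc_ids
    )
    coding_rows = [
        (lid, float(rng.uniform(-6, -1)), float(rng.uniform(-4, -1.5)))
        for lid in lnc_ids
    ]
    _filter_decoys(rng, cfg, reference, candidates, coding_rows)
    coding = pd.DataFrame(
        coding_rows, columns=["transcript_id", "cnci_like", "cpc_like"]
    ).set_index("transcript_id")
    features = {tid: "mRNA" for tid in mrna_ids}
    features.update({mid: "miRNA" for mid in mirnas})
    features.update(
        {nid: ncrna_classes[nid] for nid in ncrna_seqs}
    )
    counts, truth_de = _plant_counts(rng, cfg, features)
    evidence, truth_junctions = _plant_junctions(rng, cfg, reference, chrom_cursor)
    de_lnc = {
        r.feature_id
        for r in truth_de.itertuples()
        if r.is_de and r.rna_class == "lncRNA"
    }
    de_gene_tx = {
        r.feature_id
        for r in truth_de.itertuples()
        if r.is_de and r.rna_class == "mRNA"
    }
    de_gene = {t.replace("mRNA", "GENE") for t in de_gene_tx}
    truth_cis = _naive_cis_truth(placements, de_lnc, de_gene)
    lengths = pd.Series(
        {
            **{t: len(mrna_seqs[t]) for t in mrna_seqs},
            **{m: len(mirnas[m]) for m in mirnas},
            **{n: len(ncrna_seqs[n]) for n in ncrna_seqs},
        },
        name="length",
    )
    genome_lengths = {
        chrom: cursor + 6_000_000 for chrom, cursor in chrom_cursor.items()
    }
    return Scenario(
        config=cfg,
        mirnas=mirnas,
        mrna_seqs=mrna_seqs,
        ncrna_seqs=ncrna_seqs,
        ncrna_classes=ncrna_classes,
        reference=reference,
        candidates=candidates,
        counts=counts,
        lengths=lengths,
        class_map=features,
        coding=coding,
        junction_evidence=evidence,
        truth_target_sites=truth_targets,
        truth_sponge_sites=truth_sponges,
        truth_de=truth_de,
        truth_junctions=truth_junctions,
        truth_cis=truth_cis,
        genome_lengths=genome_lengths,
    )
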