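"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: alignment paths are
exhaustively enumerated and scored via the path scorer, overlap checks are
naive all-pairs loops, and tail probabilities are direct summations.
"""

from __future__ import annotations

import itertools
import math

from cerna_forge.target_scoring import (
    GU,
    MISMATCH,
    SCORE_TOL,
    WC,
    ScoringScheme,
    pair_state,
    score_duplex,
)


def enumerate_alignments(mirna: str, window: str, scheme: ScoringScheme, max_gaps: int):
    """Yield every (score, n_gaps, gap_positions, pairing) for the duplex.

    Paths are generated by choosing which miRNA positions are gapped and
    which window positions are bulged, then interleaving bulges with the
    forced pairing walk in every possible order.
    """
    m, w = len(mirna), len(window)
    for gm in range(max_gaps + 1):
        gt = w - (m - gm)
        if gt < 0 or gm + gt > max_gaps:
            continue
        for mir_gaps in itertools.combinations(range(1, m + 1), gm):
            for tgt_bulges in itertools.combinations(range(w), gt):
                # bulged window offsets are fixed; the pairing walk is then
                # forced, but a bulge adjacent to a gap can interleave two
                # ways -- enumerate interleavings recursively
                yield from _walk(
                    mirna, window, scheme, set(mir_gaps), set(tgt_bulges), 0, 0, ""
                )


def _walk(mirna, window, scheme, mir_gaps, tgt_bulges, i, j, path):
    m, w = len(mirna), len(window)
    if i == m and j == w:
        aln = score_duplex(mirna, window, scheme, path)
        gap_pos = tuple(k for k, s in enumerate(path) if s in "^-")
        yield (aln.score, aln.n_gaps, gap_pos, path)
        return
    # consume the next bulged window nt (window consumed from its 3' end:
    # consumption index j corresponds to window offset w-1-j)
    if j < w and (w - 1 - j) in tgt_bulges:
        yield from _walk(mirna, window, scheme, mir_gaps, tgt_bulges, i, j + 1, path + "^")
    if i < m:
        if (i + 1) in mir_gaps:
            yield from _walk(mirna, window, scheme, mir_gaps, tgt_bulges, i + 1, j, path + "-")
        elif j < w and (w - 1 - j) not in tgt_bulges:
            st = pair_state(mirna[i], window[w - 1 - j])
            yield from _walk(
                mirna, window, scheme, mir_gaps, tgt_bulges, i + 1, j + 1, path + st
            )


def best_alignment(mirna: str, window: str, scheme: ScoringScheme, max_gaps: int):
    """Minimum-penalty path under the documented tie-break order."""
    best = None
    for score, ngaps, gap_pos, path in enumerate_alignments(mirna, window, scheme, max_gaps):
        key = (round(score / SCORE_TOL), ngaps, gap_pos, path)
        if best is None or key < best[0]:
            best = (key, score, path)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# sponge rules
# ---------------------------------------------------------------------------


def sponge_paths(mir: str, window: str, rules):
    """All rule-compliant paths for one window; each yields a rank tuple.

    Enumerates every ncRNA-bulge placement (the only gap type the rules can
    ever accept) and checks rules 1-3 from scratch; miRNA-side bulges are
    structurally excluded by rule 1 so windows shorter than the miRNA never
    yield a path.
    """
    m, w = len(mir), len(window)
    b = w - m
    out = []
    if b < 0 or b > rules.max_bulge_nt * rules.max_bulges:
        return out
    slot_options = [None] if b == 0 else list(range(1, m))
    for slot in slot_options:
        # bulge after miRNA position `slot`; rule 1+3: both flanking
        # positions must lie inside the middle region
        if slot is not None and not (
            rules.in_middle(slot) and rules.in_middle(slot + 1)
        ):
            continue
        states = []
        j = 0
        for p in range(1, m + 1):
            st = pair_state(mir[p - 1], window[w - 1 - j])
            if st == GU and rules.gu_is_mismatch:
                st = MISMATCH
            states.append((p, st))
            j += 1
            if slot is not None and p == slot:
                j += b
        mm_out = sum(
            1 for p, st in states if st == MISMATCH and not rules.in_middle(p)
        )
        runs, run = [], 0
        for _, st in states:
            run = run + 1 if st == MISMATCH else 0
            runs.append(run)
        longest = max(runs) if runs else 0
        total = sum(1 for _, st in states if st == MISMATCH)
        if mm_out > rules.max_mismatches_outside_middle:
            continue
        if longest > rules.max_consecutive_mismatches:
            continue
        out.append((total, b, slot if slot is not None else m + 1, mm_out, longest))
    return out


def sponge_accepted_windows(mir: str, seq: str, rules, circular: bool = False):
    """Naive scan: every accepted (start, end, rank) before overlap merging."""
    m = len(mir)
    L = len(seq)
    scan = seq + seq if circular else seq
    out = []
    max_w = m + rules.max_bulge_nt * rules.max_bulges
    n_starts = L if circular else len(scan)
    for s in range(n_starts):
        for wlen in range(m, max_w + 1):
            if s + wlen > len(scan):
                continue
            paths = sponge_paths(mir, scan[s : s + wlen], rules)
            if paths:
                out.append((s, s + wlen, min(paths)))
    return out


def merge_best(windows):
    """Overlap-merge mirroring the documented contract (naive reimplementation)."""
    if not windows:
        return []
    windows = sorted(windows, key=lambda t: (t[0], t[1]))
    clusters = []
    cur = [windows[0]]
    end = windows[0][1]
    for t in windows[1:]:
        if t[0] < end:
            cur.append(t)
            end = max(end, t[1])
        else:
            clusters.append(cur)
            cur = [t]
            end = t[1]
    clusters.append(cur)
    return [min(c, key=lambda t: (t[2][:3], t[0])) for c in clusters]


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def binom_two_sided(a: int, n: int, p0: float) -> float:
    """Direct tail summation of the two-sided exact binomial p-value."""
    if n == 0:
        return 1.0
    probs = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
    obs = probs[a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-7)))


def naive_cis_edges(lnc_spans, gene_spans, window):
    """All-pairs window check; spans are (id, chrom, start, end)."""
    out = set()
    for lid, lc, ls, le in lnc_spans:
        for gid, gc, gs, ge in gene_spans:
            if lc != gc:
                continue
            gap = max(gs - le, ls - ge, 0)
            if gap <= window:
                out.add((lid, gid))
    return out


def naive_circ_calls(evidence, max_mismatch=2, min_reads=1, max_span=100_000):
    """Group-filter reimplementation of the circRNA criteria."""
    groups = {}
    for ev in evidence:
        if ev.donor - ev.acceptor <= 0 or ev.mismatches > max_mismatch:
            continue
        groups.setdefault((ev.chrom, ev.strand, ev.acceptor, ev.donor), []).append(ev)
    return {
        key: len(reads)
        for key, reads in groups.items()
        if len(reads) >= min_reads and key[3] - key[2] < max_span
    }


def naive_class_code(cand, refs):
    """Priority-ordered class code by direct interval arithmetic."""
    same = [r for r in refs if r.chrom == cand.chrom and r.strand == cand.strand]
    anti = [r for r in refs if r.chrom == cand.chrom and r.strand != cand.strand]
    if any(r.exons == cand.exons for r in same):
        return "="
    if len(cand.exons) > 1:
        cj = set(cand.introns())
        if any(cj & set(r.introns()) for r in same):
            return "j"
    def exonic_overlap(a, b):
        return any(
            s1 < e2 and s2 < e1 for s1, e1 in a.exons for s2, e2 in b.exons
        )
    if any(exonic_overlap(cand, r) for r in same):
        return "o"
    for r in same:
        for intron in r.introns():
            if intron[0] <= cand.start and cand.end <= intron[1]:
                return "i"
    if any(exonic_overlap(cand, r) for r in anti):
        return "x"
    return "u"
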