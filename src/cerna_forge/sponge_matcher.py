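"""miRNA sponge-site detection on lncRNAs and circRNAs.

A sponge site (miRNA response element on a non-coding RNA) is accepted when a
pairing path of the miRNA against the window satisfies three rules:

1. bulges may occur only on the ncRNA strand and only in the middle of the
   miRNA (default positions 9-12, 1-based from the miRNA 5' end);
2. at most four mismatches outside the middle region, and no run of more
   than two consecutive mismatches anywhere;
3. no bulges outside the middle region (and never on the miRNA strand).

G:U wobbles count as matches for these rules by default. circRNA sequences
are scanned across the back-splice junction by doubling the sequence and
folding coordinates modulo the original length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import SequenceSet
from .target_scoring import GU, MISMATCH, WC, _as_rna, pair_state

__all__ = ["SpongeRuleSet", "SpongeSite", "match_sponge_sites", "circularize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpongeRuleSet:
    """Parameters of the three sponge-matching rules.

    ``middle_start``/``middle_end`` delimit "the middle of the miRNA" in
    1-based miRNA coordinates. A bulge of up to ``max_bulge_nt`` ncRNA
    nucleotides may sit between two adjacent middle positions; at most
    ``max_bulges`` bulges per site.
    """

    middle_start: int = 9
    middle_end: int = 12
    max_mismatches_outside_middle: int = 4
    max_consecutive_mismatches: int = 2
    max_bulge_nt: int = 2
    max_bulges: int = 1
    gu_is_mismatch: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.middle_start <= self.middle_end):
            raise ValueError("need 1 <= middle_start <= middle_end")
        if min(
            self.max_mismatches_outside_middle,
            self.max_consecutive_mismatches,
            self.max_bulge_nt,
            self.max_bulges,
        ) < 0:
            raise ValueError("rule counts must be >= 0")

    def in_middle(self, position: int) -> bool:
        return self.middle_start <= position <= self.middle_end


@dataclass
class SpongeSite:
    """One accepted sponge site and its rule bookkeeping.

    ``window`` is [start, end) on the ncRNA; for circRNAs a junction-spanning
    site has ``end`` folded modulo the circle length (so end < start flags a
    wrapped site). ``pairing`` runs along the miRNA 5'->3' with the symbols of
    :mod:`cerna_forge.target_scoring` (``^`` marks a bulged ncRNA
    nucleotide).
    """

    mirna_id: str
    ncrna_id: str
    ncrna_class: str  # "lncRNA" | "circRNA"
    window: tuple[int, int]
    pairing: str
    mismatches_outside_middle: int
    mismatches_total: int
    longest_mismatch_run: int
    bulges: list[tuple[int, int]] = field(default_factory=list)  # (after miRNA pos, size)

    @property
    def bulge_nt(self) -> int:
        return sum(size for _, size in self.bulges)


def _evaluate_window(
    mir: str, window: str, rules: SpongeRuleSet
) -> tuple[tuple, str, int, int, int, list[tuple[int, int]]] | None:
    """Best rule-compliant pairing path for one window, or None.

    Enumerates bulge placements directly: with bulges confined to the ncRNA
    strand between adjacent middle positions, a window of length m+b admits a
    single bulge of b nucleotides at each admissible middle slot (b = 0 means
    the plain 1:1 pairing). Paths are ranked by (mismatches, bulge
    nucleotides, leftmost bulge); the mismatch run cap is global, the budget
    applies outside the middle only.
    """
    m = len(mir)
    w = len(window)
    b = w - m
    if b < 0 or (b > 0 and (rules.max_bulges < 1 or b > rules.max_bulge_nt)):
        return None
    if b == 0:
        slots: list[int | None] = [None]
    else:
        # bulge between middle positions p and p+1 (both inside the middle)
        slots = [
            p
            for p in range(rules.middle_start, rules.middle_end)
            if p + 1 <= rules.middle_end and p < m
        ]
        if not slots:
            return None
    best = None
    for slot in slots:
        # walk the path miRNA 5'->3' against the window 3'->5'; the bulge
        # (if any) consumes b window nucleotides after miRNA position `slot`
        path_syms: list[str] = []
        j = 0  # window nts consumed, counted from the window's 3' end
        mm_total = 0
        mm_outside = 0
        run = 0
        longest = 0
        violated = False
        for p in range(1, m + 1):
            st = pair_state(mir[p - 1], window[w - 1 - j])
            if st == GU and rules.gu_is_mismatch:
                st = MISMATCH
            path_syms.append(st)
            j += 1
            if st == MISMATCH:
                mm_total += 1
                if not rules.in_middle(p):
                    mm_outside += 1
                run += 1
                longest = max(longest, run)
                # both rule counters only grow along the walk, so bail early
                if (
                    mm_outside > rules.max_mismatches_outside_middle
                    or longest > rules.max_consecutive_mismatches
                ):
                    violated = True
                    break
            else:
                run = 0
            if slot is not None and p == slot:
                path_syms.append("^" * b)
                j += b
        if violated:
            continue
        bulges = [] if slot is None else [(slot, b)]
        key = (mm_total, b, slot if slot is not None else m + 1)
        cand = (key, "".join(path_syms), mm_outside, mm_total, longest, bulges)
        if best is None or key < best[0]:
            best = cand
    return best


def match_sponge_sites(
    mirnas: SequenceSet,
    ncrnas: SequenceSet,
    rules: SpongeRuleSet | None = None,
    classes: dict[str, str] | None = None,
) -> list[SpongeSite]:
    """Scan ncRNAs for rule-compliant miRNA sponge sites.

    ``classes`` maps ncRNA id -> "lncRNA" | "circRNA" (default lncRNA).
    circRNA sequences are treated as circular: the scan wraps across the
    back-splice junction and wrapped sites report folded coordinates.
    Overlapping accepted windows of one (miRNA, ncRNA) pair are collapsed to
    the best path (fewest mismatches, then fewest bulge nucleotides, then
    leftmost).
    """
    rules = rules or SpongeRuleSet()
    classes = classes or {}
    out: list[SpongeSite] = []
    for mirna_id, mir_raw in mirnas.items():
        mir = _as_rna(mir_raw)
        m = len(mir)
        for nid, seq_raw in ncrnas.items():
            ncls = classes.get(nid, "lncRNA")
            circular = ncls == "circRNA"
            L = len(seq_raw)
            if L < m and not circular:
                log.warning(
                    "ncRNA %s (%d nt) shorter than miRNA %s; skipped", nid, L, mirna_id
                )
                continue
            scan_seq, fold = (circularize(seq_raw) if circular else (seq_raw, None))
            scan_seq = _as_rna(scan_seq)
            max_w = m + (rules.max_bulge_nt if rules.max_bulges > 0 else 0)
            candidates = []
            n_starts = L if circular else len(scan_seq)
            for s in range(n_starts):
                for wlen in range(m, max_w + 1):
                    e = s + wlen
                    if e > len(scan_seq):
                        continue
                    res = _evaluate_window(mir, scan_seq[s:e], rules)
                    if res is None:
                        continue
                    key, pairing, mm_out, mm_tot, longest, bulges = res
                    candidates.append((s, e, key, pairing, mm_out, mm_tot, longest, bulges))
            for s, e, key, pairing, mm_out, mm_tot, longest, bulges in _merge_windows(
                candidates
            ):
                window = (s, fold(e)) if (fold and e > L) else (s, e)
                out.append(
                    SpongeSite(
                        mirna_id=mirna_id,
                        ncrna_id=nid,
                        ncrna_class=ncls,
                        window=window,
                        pairing=pairing,
                        mismatches_outside_middle=mm_out,
                        mismatches_total=mm_tot,
                        longest_mismatch_run=longest,
                        bulges=bulges,
                    )
                )
    out.sort(key=lambda s: (s.mirna_id, s.ncrna_id, s.window))
    return out


def _merge_windows(candidates):
    """Collapse overlapping accepted windows to the best-ranked one."""
    if not candidates:
        return []
    candidates = sorted(candidates, key=lambda c: (c[0], c[1]))
    merged = []
    cluster = [candidates[0]]
    cluster_end = candidates[0][1]
    for c in candidates[1:]:
        if c[0] < cluster_end:
            cluster.append(c)
            cluster_end = max(cluster_end, c[1])
        else:
            merged.append(min(cluster, key=lambda c: (c[2], c[0])))
            cluster = [c]
            cluster_end = c[1]
    merged.append(min(cluster, key=lambda c: (c[2], c[0])))
    return merged


def circularize(sequence: str):
    """Double a circRNA sequence for junction-spanning scans.

    Returns ``(doubled, fold)`` where ``fold`` maps a coordinate on the
    doubled sequence back onto the circle (modulo the original length). Sites
    whose start lies in the second copy are duplicates and are never
    generated by :func:`match_sponge_sites` (it only starts windows in the
    first copy).
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    return sequence + sequence, (lambda x: x % L)
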