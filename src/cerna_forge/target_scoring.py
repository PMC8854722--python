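"""Penalty-scored miRNA/target duplex alignment and target-site prediction.

The scoring standard used throughout plant small-RNA target prediction counts
imperfections of the miRNA:target duplex instead of hybridisation energy:

* a mismatch or a missing nucleotide (bulge on either strand) costs 1 point,
* a G:U wobble pair costs 0.5 points,
* penalties that fall inside the core region of the miRNA (positions 2-13,
  counted 1-based from the miRNA 5' end) are doubled,
* a site is retained when its total penalty is at most 4 points.

Positions are always counted along the miRNA 5'->3'; the miRNA 5' end pairs
with the 3' end of the target window, so the target window is traversed
3'->5' while scoring.

``align_site`` finds the minimum-penalty pairing path for one window by
dynamic programming; ``predict_targets`` scans whole transcripts with an
exact vectorised pre-scan so only candidate windows reach the full DP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceSet

__all__ = [
    "WC",
    "GU",
    "MISMATCH",
    "TARGET_BULGE",
    "MIRNA_GAP",
    "ScoringScheme",
    "DuplexAlignment",
    "pair_state",
    "score_duplex",
    "align_site",
    "predict_targets",
]

log = logging.getLogger(__name__)

# pairing-state symbols; a pairing path is the concatenation of these,
# read along the miRNA 5'->3'
WC = "|"           # Watson-Crick pair
GU = "o"           # G:U wobble pair
MISMATCH = "x"     # paired but neither WC nor wobble
TARGET_BULGE = "^" # unpaired target nucleotide (bulged out of the duplex)
MIRNA_GAP = "-"    # unpaired miRNA nucleotide (gap on the target strand)

SCORE_TOL = 1e-9

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_DNA2RNA = str.maketrans("Tt", "Uu")


def _as_rna(seq: str) -> str:
    return seq.upper().translate(_DNA2RNA)


def pair_state(mirna_nt: str, target_nt: str) -> str:
    """Classify one opposed nucleotide pair as WC, GU or MISMATCH.

    Both nucleotides are read in RNA alphabet; ``N`` never pairs.
    """
    if _COMPLEMENT.get(mirna_nt) == target_nt:
        return WC
    if (mirna_nt, target_nt) in (("G", "U"), ("U", "G")):
        return GU
    return MISMATCH


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty scheme for duplex alignment.

    ``core_applies_to`` selects whether the core doubling applies to every
    penalty state (``"all"``, the default, as in the classical scoring
    standard) or to G:U wobbles only (``"gu_only"``, the narrowest reading of
    the rule text).
    """

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    indel_penalty: float = 1.0
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0
    max_score: float = 4.0
    core_applies_to: str = "all"  # "all" | "gu_only"

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.indel_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if not (1 <= self.core_start <= self.core_end):
            raise ValueError("need 1 <= core_start <= core_end")
        if self.core_applies_to not in ("all", "gu_only"):
            raise ValueError("core_applies_to must be 'all' or 'gu_only'")

    def in_core(self, position: int) -> bool:
        """Is the 1-based miRNA position inside the core region?"""
        return self.core_start <= position <= self.core_end

    def penalty(self, state: str, position: int) -> float:
        """Penalty of one path state attributed to a 1-based miRNA position."""
        if state == WC:
            return 0.0
        base = {
            GU: self.gu_penalty,
            MISMATCH: self.mismatch_penalty,
            TARGET_BULGE: self.indel_penalty,
            MIRNA_GAP: self.indel_penalty,
        }[state]
        doubled = self.in_core(position) and (
            self.core_applies_to == "all" or state == GU
        )
        return base * self.core_multiplier if doubled else base


@dataclass
class DuplexAlignment:
    """One candidate binding site: the pairing path and its penalty breakdown.

    ``pairing`` runs along the miRNA 5'->3' (so its first symbol describes
    miRNA position 1, which pairs the last nucleotide of the window);
    ``target_window`` is the [start, end) slice of the transcript.
    """

    mirna_id: str
    target_id: str
    target_window: tuple[int, int]
    pairing: str
    score: float
    breakdown: dict[str, float] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return self.pairing.count(TARGET_BULGE) + self.pairing.count(MIRNA_GAP)


def score_duplex(
    mirna_seq: str,
    window_seq: str,
    scheme: ScoringScheme,
    pairing: str,
    *,
    mirna_id: str = "miRNA",
    target_id: str = "target",
    window_start: int = 0,
) -> DuplexAlignment:
    """Score one explicit pairing path of a miRNA against a target window.

    The path must consume the full miRNA and the full window, and each paired
    state must agree with the actual nucleotides (a ``|`` over a non-WC pair
    is an error). Bulge penalties are attributed to the next miRNA position
    the path consumes (or the last position for a bulge at the path's end).
    """
    mir = _as_rna(mirna_seq)
    tgt = _as_rna(window_seq)  # window 5'->3'; consumed from its 3' end
    m, w = len(mir), len(tgt)
    i = 0  # miRNA nts consumed (5'->3')
    j = 0  # target nts consumed (3'->5')
    total = 0.0
    breakdown = {WC: 0.0, GU: 0.0, MISMATCH: 0.0, TARGET_BULGE: 0.0, MIRNA_GAP: 0.0}
    for state in pairing:
        if state in (WC, GU, MISMATCH):
            if i >= m or j >= w:
                raise ValueError("pairing path overruns miRNA/window")
            observed = pair_state(mir[i], tgt[w - 1 - j])
            if observed != state:
                raise ValueError(
                    f"path state {state!r} at miRNA position {i + 1} "
                    f"disagrees with nucleotides ({observed!r})"
                )
            pos = i + 1
            i += 1
            j += 1
        elif state == MIRNA_GAP:
            if i >= m:
                raise ValueError("pairing path overruns miRNA")
            pos = i + 1
            i += 1
        elif state == TARGET_BULGE:
            if j >= w:
                raise ValueError("pairing path overruns window")
            pos = min(i + 1, m)  # next miRNA position, capped at the 3' end
            j += 1
        else:
            raise ValueError(f"unknown pairing state {state!r}")
        p = scheme.penalty(state, pos)
        total += p
        breakdown[state] += p
    if i != m:
        raise ValueError(f"pairing path consumed {i}/{m} miRNA nucleotides")
    if j != w:
        raise ValueError(f"pairing path consumed {j}/{w} window nucleotides")
    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        target_window=(window_start, window_start + w),
        pairing=pairing,
        score=total,
        breakdown={k: v for k, v in breakdown.items() if v > 0},
    )


def _score_key(score: float) -> int:
    return int(round(score / SCORE_TOL))


def align_site(
    mirna_seq: str,
    window_seq: str,
    scheme: ScoringScheme | None = None,
    max_gaps: int = 2,
    **ids,
) -> DuplexAlignment:
    """Minimum-penalty pairing path for one miRNA against one window.

    Dynamic programme over (miRNA consumed, window consumed, gaps used); ties
    are broken by fewer gaps, then leftmost gap placement along the path, then
    the lexicographically smallest pairing string.
    """
    scheme = scheme or ScoringScheme()
    if max_gaps < 0:
        raise ValueError("max_gaps must be >= 0")
    mir = _as_rna(mirna_seq)
    tgt = _as_rna(window_seq)
    m, w = len(mir), len(tgt)
    if not (m - max_gaps <= w <= m + max_gaps):
        raise ValueError(
            f"window length {w} incompatible with miRNA length {m} "
            f"and max_gaps {max_gaps}"
        )
    # cell value: (score_key, n_gaps, gap_path_positions, pairing) -- tuple
    # comparison implements the documented tie-break order; cells are expanded
    # in increasing i+j, which every transition strictly increases
    cells: dict[tuple[int, int, int], tuple] = {(0, 0, 0): (0, 0, (), "")}
    by_total: list[list[tuple[int, int, int]]] = [[] for _ in range(m + w + 1)]
    by_total[0].append((0, 0, 0))

    def relax(key: tuple[int, int, int], cand: tuple) -> None:
        if key not in cells:
            cells[key] = cand
            by_total[key[0] + key[1]].append(key)
        elif cand < cells[key]:
            cells[key] = cand

    for total in range(m + w + 1):
        for key in by_total[total]:
            i, j, g = key
            sk, ng, gp, path = cells[key]
            step = len(path)
            if i < m and j < w:
                st = pair_state(mir[i], tgt[w - 1 - j])
                relax(
                    (i + 1, j + 1, g),
                    (sk + _score_key(scheme.penalty(st, i + 1)), ng, gp, path + st),
                )
            if g < max_gaps and i < m:
                relax(
                    (i + 1, j, g + 1),
                    (
                        sk + _score_key(scheme.penalty(MIRNA_GAP, i + 1)),
                        ng + 1,
                        gp + (step,),
                        path + MIRNA_GAP,
                    ),
                )
            if g < max_gaps and j < w:
                relax(
                    (i, j + 1, g + 1),
                    (
                        sk + _score_key(scheme.penalty(TARGET_BULGE, min(i + 1, m))),
                        ng + 1,
                        gp + (step,),
                        path + TARGET_BULGE,
                    ),
                )
    finals = [
        v for (i, j, _g), v in cells.items() if i == m and j == w
    ]
    if not finals:
        raise ValueError("no pairing path consumes both sequences")  # pragma: no cover
    sk, _ng, _gp, path = min(finals)
    return score_duplex(
        mirna_seq,
        window_seq,
        scheme,
        path,
        mirna_id=ids.get("mirna_id", "miRNA"),
        target_id=ids.get("target_id", "target"),
        window_start=ids.get("window_start", 0),
    )


# ---------------------------------------------------------------------------
# transcript scanning
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq.upper()), dtype=np.int8, count=len(seq))


def _scan_min_scores(
    mir: str, transcript: str, scheme: ScoringScheme, max_gaps: int
) -> np.ndarray:
    """Exact minimum duplex penalty over windows ending at each transcript offset.

    Semi-global DP vectorised over the transcript axis. The miRNA is consumed
    from its 3' end while the transcript is traversed 5'->3', which matches
    the antiparallel duplex geometry. Returns an array ``s`` of shape
    (len(transcript)+1,): ``s[j]`` is the minimum penalty over all windows
    ending at j (any admissible window length, any <= max_gaps gaps).
    """
    mirna = _as_rna(mir)
    m = len(mirna)
    tgt_codes = _encode(_as_rna(transcript))
    L = len(tgt_codes)

    def mult(pos: int, state: str) -> float:
        doubled = scheme.in_core(pos) and (
            scheme.core_applies_to == "all" or state == GU
        )
        return scheme.core_multiplier if doubled else 1.0

    INF = np.inf
    G = max_gaps
    # dp[g][j]: min penalty, k miRNA 3'-nts consumed, j transcript nts consumed
    dp = [np.zeros(L + 1) if g == 0 else np.full(L + 1, INF) for g in range(G + 1)]
    # bulge relaxation at level k=0 (bulge after miRNA position m on the path)
    for g in range(G):
        cost = scheme.indel_penalty * mult(m, TARGET_BULGE)
        relaxed = dp[g][:-1] + cost
        dp[g + 1][1:] = np.minimum(dp[g + 1][1:], relaxed)
    for k in range(m):
        pos = m - k  # 1-based miRNA position consumed at this level
        pair_states = [pair_state(mirna[m - 1 - k], c) for c in "ACGUN"]
        pair_costs = np.array(
            [
                {WC: 0.0, GU: scheme.gu_penalty, MISMATCH: scheme.mismatch_penalty}[st]
                * mult(pos, st)
                for st in pair_states
            ]
        )[tgt_codes]
        new = [np.full(L + 1, INF) for _ in range(G + 1)]
        gap_cost = scheme.indel_penalty * mult(pos, MIRNA_GAP)
        for g in range(G + 1):
            # pair transition
            new[g][1:] = dp[g][:-1] + pair_costs
            # miRNA-gap transition
            if g > 0:
                new[g] = np.minimum(new[g], dp[g - 1] + gap_cost)
        # target-bulge relaxation within the new level (k+1 miRNA 3'-nts
        # consumed): on the 5'->3' path such a bulge sits just before the
        # consumed block, whose first position is pos = m-k, so the forward
        # attribution (next consumed miRNA position) is pos
        bulge_cost = scheme.indel_penalty * mult(pos, TARGET_BULGE)
        for g in range(G):
            relaxed = new[g][:-1] + bulge_cost
            new[g + 1][1:] = np.minimum(new[g + 1][1:], relaxed)
        dp = new
    out = dp[0]
    for g in range(1, G + 1):
        out = np.minimum(out, dp[g])
    return out


def predict_targets(
    mirnas: SequenceSet,
    transcripts: SequenceSet,
    scheme: ScoringScheme | None = None,
    max_gaps: int = 2,
    region: dict[str, list[tuple[int, int]]] | None = None,
) -> list[DuplexAlignment]:
    """Scan transcripts for miRNA binding sites with penalty <= the cutoff.

    ``region`` optionally restricts scanning to intervals per transcript
    (e.g. annotated 3' UTRs); by default whole transcripts are scanned.
    Overlapping retained sites of the same (miRNA, transcript) pair are merged
    to the lowest-scoring one (ties: leftmost). Output is sorted by
    (miRNA id, target id, window start).
    """
    scheme = scheme or ScoringScheme()
    if len(mirnas) == 0 or len(transcripts) == 0:
        raise ValueError("empty input sequence set")
    results: list[DuplexAlignment] = []
    for mirna_id, mir in mirnas.items():
        m = len(mir)
        for tid, full_seq in transcripts.items():
            if region is None:
                intervals = [(0, len(full_seq))]
            else:
                intervals = region.get(tid)
                if intervals is None:
                    log.warning("no scan region for transcript %s; skipped", tid)
                    continue
            for iv_start, iv_end in intervals:
                seq = full_seq[iv_start:iv_end]
                if len(seq) < m - max_gaps:
                    log.warning(
                        "transcript %s (%d nt) shorter than miRNA %s minus gaps; skipped",
                        tid, len(seq), mirna_id,
                    )
                    continue
                ends = _scan_min_scores(mir, seq, scheme, max_gaps)
                hit_ends = np.nonzero(ends <= scheme.max_score + SCORE_TOL)[0]
                seen: set[tuple[int, int]] = set()
                sites: list[DuplexAlignment] = []
                for j in hit_ends:
                    for wlen in range(m - max_gaps, m + max_gaps + 1):
                        s = int(j) - wlen
                        if s < 0 or (s, int(j)) in seen:
                            continue
                        seen.add((s, int(j)))
                        aln = align_site(
                            mir,
                            seq[s : int(j)],
                            scheme,
                            max_gaps,
                            mirna_id=mirna_id,
                            target_id=tid,
                            window_start=s + iv_start,
                        )
                        if aln.score <= scheme.max_score + SCORE_TOL:
                            sites.append(aln)
                results.extend(_merge_overlapping(sites))
    results.sort(key=lambda a: (a.mirna_id, a.target_id, a.target_window))
    return results


def _merge_overlapping(sites: list[DuplexAlignment]) -> list[DuplexAlignment]:
    """Collapse clusters of mutually overlapping sites to their best member."""
    if not sites:
        return []
    sites = sorted(sites, key=lambda a: a.target_window)
    # lowest score wins; ties prefer the ungapped (then leftmost) duplex
    def rank(a: DuplexAlignment):
        return (_score_key(a.score), a.n_gaps, a.target_window)

    merged: list[DuplexAlignment] = []
    cluster = [sites[0]]
    cluster_end = sites[0].target_window[1]
    for aln in sites[1:]:
        if aln.target_window[0] < cluster_end:
            cluster.append(aln)
            cluster_end = max(cluster_end, aln.target_window[1])
        else:
            merged.append(min(cluster, key=rank))
            cluster = [aln]
            cluster_end = aln.target_window[1]
    merged.append(min(cluster, key=rank))
    return merged
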