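"""Two-library differential expression with per-RNA-class thresholds.

The study design is a single anther library ('Ant') against a single
vegetative-tissue library ('Mix'), so no replicate-based dispersion can be
estimated. Fold changes are computed on normalized, pseudocounted abundances
and significance comes from an exact conditional test:

* ``poisson_exact`` (default): conditional on the two-library sum, the count
  in one library is Binomial(n, N_a / (N_a + N_b)); the two-sided p-value
  sums all outcomes no more probable than the observed one (the classic
  exact test for two Poisson rates);
* ``nb_exact``: the analogous conditional test for two negative-binomial
  counts with a supplied common dispersion.

Classification then applies the per-class thresholds with the printed
strict/inclusive comparisons: mRNA |log2FC| > 2 and p <= 0.01; miRNA,
lncRNA and circRNA |log2FC| > 1 and p <= 0.05. Features with all reads in
one library are additionally flagged as library-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable

__all__ = [
    "DEThresholds",
    "DifferentialCall",
    "normalize",
    "poisson_exact_pvalue",
    "nb_exact_pvalue",
    "test_differential",
    "summarize_de",
]

KNOWN_CLASSES = ("mRNA", "miRNA", "lncRNA", "circRNA")


@dataclass(frozen=True)
class DEThresholds:
    """Per-class (|log2FC| threshold, p threshold); comparisons are strict on
    fold change and inclusive on p, exactly as printed in the protocol."""

    per_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mRNA": (2.0, 0.01),
            "miRNA": (1.0, 0.05),
            "lncRNA": (1.0, 0.05),
            "circRNA": (1.0, 0.05),
        }
    )
    pseudocount: float = 1.0

    def for_class(self, rna_class: str) -> tuple[float, float]:
        if rna_class not in self.per_class:
            raise ValueError(
                f"unknown RNA class {rna_class!r}; known: {sorted(self.per_class)}"
            )
        return self.per_class[rna_class]


@dataclass
class DifferentialCall:
    feature_id: str
    rna_class: str
    norm_a: float
    norm_b: float
    log2fc: float  # B over A
    p_value: float
    status: str    # "up" | "down" | "ns"
    specific: str  # "none" | "A_only" | "B_only"


def normalize(counts: CountTable, method: str = "cpm") -> pd.DataFrame:
    """Depth-normalize a count table: counts-per-million or FPKM."""
    totals = counts.counts.sum(axis=0)
    if method == "cpm":
        return counts.counts * 1e6 / totals
    if method == "fpkm":
        if counts.lengths is None:
            raise ValueError("fpkm normalization requires feature lengths")
        if counts.lengths.isna().any():
            missing = list(counts.lengths.index[counts.lengths.isna()])[:5]
            raise ValueError(f"missing lengths for {missing}")
        return (
            counts.counts * 1e9 / totals
        ).div(counts.lengths, axis=0)
    raise ValueError("method must be 'cpm' or 'fpkm'")


def poisson_exact_pvalue(a: int, b: int, total_a: int, total_b: int) -> float:
    """Two-sided conditional binomial test of two Poisson counts."""
    n = a + b
    if n == 0:
        return 1.0
    p0 = total_a / (total_a + total_b)
    return stats.binomtest(a, n, p0, alternative="two-sided").pvalue


def nb_exact_pvalue(
    a: int, b: int, total_a: int, total_b: int, dispersion: float
) -> float:
    """Two-sided exact test for two NB counts sharing a common dispersion.

    Conditions on the observed sum: P(A = k | A + B = a + b) is computed by
    normalizing the joint NB probabilities over k = 0..a+b; the p-value sums
    the conditional probabilities of all outcomes no more probable than the
    observed one. ``dispersion`` <= 0 falls back to the Poisson exact test.
    """
    if dispersion <= 0:
        return poisson_exact_pvalue(a, b, total_a, total_b)
    n = a + b
    if n == 0:
        return 1.0
    rate = n / (total_a + total_b)
    mu_a, mu_b = rate * total_a, rate * total_b
    r = 1.0 / dispersion
    k = np.arange(n + 1)
    logp = stats.nbinom.logpmf(k, r, r / (r + mu_a)) + stats.nbinom.logpmf(
        n - k, r, r / (r + mu_b)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[a]
    return float(probs[probs <= obs * (1 + 1e-8)].sum())


def test_differential(
    counts: CountTable,
    class_map: dict[str, str],
    thresholds: DEThresholds | None = None,
    test: str = "poisson_exact",
    dispersion: float = 0.0,
    norm_method: str = "cpm",
    numerator: str | None = None,
) -> list[DifferentialCall]:
    """Call differential expression between exactly two libraries.

    ``numerator`` names the library whose abundance forms the numerator of
    the fold change (default: the second column, matching an 'Ant' over
    'Mix' orientation when columns are ordered that way).
    """
    thresholds = thresholds or DEThresholds()
    if test not in ("poisson_exact", "nb_exact"):
        raise ValueError("test must be 'poisson_exact' or 'nb_exact'")
    libs = counts.libraries
    if len(libs) != 2:
        raise ValueError(f"exactly two libraries required, got {libs}")
    lib_b = numerator if numerator is not None else libs[1]
    if lib_b not in libs:
        raise ValueError(f"numerator {lib_b!r} not among libraries {libs}")
    lib_a = libs[0] if lib_b == libs[1] else libs[1]
    for f, c in class_map.items():
        if c not in thresholds.per_class:
            raise ValueError(
                f"unknown RNA class {c!r} for {f!r}; known: "
                f"{sorted(thresholds.per_class)}"
            )
    norm = normalize(counts, norm_method)
    total_a = int(counts.counts[lib_a].sum())
    total_b = int(counts.counts[lib_b].sum())
    pc = thresholds.pseudocount
    calls: list[DifferentialCall] = []
    for fid in counts.features:
        if fid not in class_map:
            continue
        cls = class_map[fid]
        lfc_thr, p_thr = thresholds.for_class(cls)
        a = int(counts.counts.at[fid, lib_a])
        b = int(counts.counts.at[fid, lib_b])
        na, nb_ = float(norm.at[fid, lib_a]), float(norm.at[fid, lib_b])
        lfc = float(np.log2((nb_ + pc) / (na + pc)))
        if test == "poisson_exact":
            p = poisson_exact_pvalue(a, b, total_a, total_b)
        else:
            p = nb_exact_pvalue(a, b, total_a, total_b, dispersion)
        if p <= p_thr and lfc > lfc_thr:
            status = "up"
        elif p <= p_thr and -lfc > lfc_thr:
            status = "down"
        else:
            status = "ns"
        if a == 0 and b > 0:
            specific = "B_only"
        elif b == 0 and a > 0:
            specific = "A_only"
        else:
            specific = "none"
        calls.append(
            DifferentialCall(fid, cls, na, nb_, lfc, p, status, specific)
        )
    return calls


def summarize_de(calls: list[DifferentialCall]) -> pd.DataFrame:
    """Per-class partition of calls: up, down, ns, library-specific counts."""
    rows = []
    classes = sorted({c.rna_class for c in calls})
    for cls in classes:
        sub = [c for c in calls if c.rna_class == cls]
        rows.append(
            {
                "rna_class": cls,
                "up": sum(c.status == "up" for c in sub),
                "down": sum(c.status == "down" for c in sub),
                "ns": sum(c.status == "ns" for c in sub),
                "specific_A": sum(c.specific == "A_only" for c in sub),
                "specific_B": sum(c.specific == "B_only" for c in sub),
                "total": len(sub),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rna_class", "up", "down", "ns", "specific_A", "specific_B", "total"],
    )


def de_features(calls: list[DifferentialCall]) -> set[str]:
    """Identifiers of features called differentially expressed (up or down)."""
    return {c.feature_id for c in calls if c.status in ("up", "down")}
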