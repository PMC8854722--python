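# Methods notes

## Duplex scoring and target prediction

The scorer counts imperfections of the miRNA:target duplex: 1 point per
mismatch or missing nucleotide, 0.5 per G:U wobble, doubled inside the core
region (miRNA positions 2–13, 1-based from the 5' end), retention cutoff
4 points. Two modelling choices were genuinely open and are both exposed:

* **Core doubling scope.** The rule text names only G:U in the core, but
  the progenitor scoring standard doubles *all* core penalties. The default
  is `core_applies_to="all"`, with `"gu_only"` available; the choice is
  stamped into stage output headers.
* **Missing nucleotides.** "Missing nt" is modelled as two states with equal
  cost: a bulged target nucleotide (`^`) and an unpaired miRNA nucleotide
  (`-`). A bulge's penalty is attributed to the next miRNA position the
  path consumes (core doubling applies accordingly).

`align_site` is an exact dynamic programme over (miRNA consumed, window
consumed, gaps used) with ≤ `max_gaps` (default 2) gap nucleotides. Ties
are broken by fewer gaps, then leftmost gap placement, then the
lexicographically smallest pairing string — fully deterministic. Scores are
compared with a 1e-9 tolerance; under the default scheme all scores are
multiples of 0.5.

`predict_targets` scans whole transcripts (a 3'UTR-interval restriction is
available). A vectorised semi-global DP computes the *exact* minimum
penalty for every window end first; only ends at or below the cutoff reach
the tie-broken alignment, so the pre-scan is a filter in speed only, never
in result. Overlapping retained sites of one (miRNA, transcript) pair are
merged to the lowest-scoring site, preferring ungapped alignments and then
the leftmost window on ties — an equal-score gapped sub-window of a planted
site therefore never displaces it.

## Sponge matching

Rules: (1) bulges only on the ncRNA strand and only "in the middle of the
miRNA"; (2) ≤ 4 mismatches outside the middle and no run of > 2 consecutive
mismatches; (3) no bulges elsewhere. Decisions taken where the rule text is
silent:

* **"Middle"** is undefined in the protocol; default positions 9–12, the
  canonical central-bulge region of endogenous target mimics. Configurable
  and stamped into output.
* The mismatch **budget** applies outside the middle only; the
  consecutive-run cap is position-independent, since that clause is not
  position-qualified. G:U counts as a match (`gu_is_mismatch=false`).
* **Bulge geometry**: at most 1 bulge of ≤ 2 nt per site by default, placed
  between two adjacent middle positions. This keeps the brute-force oracle
  tractable and covers the central-bulge mimic geometry.
* All accepted non-overlapping sites per (miRNA, ncRNA) pair are reported;
  overlapping windows collapse to the path with fewest mismatches, then
  fewest bulge nucleotides, then leftmost.

circRNA sequences are scanned as circles: the sequence is doubled, windows
start only in the first copy, and junction-spanning sites report
end-coordinates folded modulo the circle length (`end < start` marks a
wrapped site).

These rules are permissive: on realistic-length random-background ncRNAs,
rule-compliant windows arise by chance at an appreciable rate (roughly one
per few kilobases of miRNA×ncRNA scan). This is a property of the rule set,
not of the implementation; the synthetic generator therefore records such
incidental sites in its truth tables (kind `incidental`) rather than
pretending clean backgrounds exist.

## lncRNA filtering

Class codes are assigned by priority (=, j, o, i, x, u): exact exon-chain
match; shared splice junction; other same-strand exonic overlap; intronic;
antisense exonic overlap; intergenic. The filter applies, in order:
length ≥ 200 bp → class code ∈ {i, j, o, u, x} → coding-potential
predicate, with per-step removal counts in an audit table. The retained set
is order-independent (the predicate is a conjunction); the audit counts are
order-dependent by design.

The protocol's deletion predicate — delete when CNCI < 0 *and* CPC < −1 —
is the opposite of the usual sign convention (negative scores mean
noncoding). `filter_lncrna` implements the predicate exactly as printed as
the default (`convention="literal"`) and offers `convention="standard"`,
which keeps only conventionally noncoding transcripts (CNCI < 0 and
CPC < −1). The synthetic generator emits conventionally signed scores, so
its scenarios are filtered with the standard convention. Pfam-style domain
filtering is out of scope and noted in the audit. ORFs are the longest
complete ATG→stop reading frame in the three forward frames; an ATG without
an in-frame stop does not count.

## circRNA calling

Evidence is a plain table of chimeric reads (read id, chromosome, strand,
acceptor, donor, per-read mismatches); the upstream chimeric aligner is out
of scope. Reads with mismatches > 2 are discarded *before* grouping;
groups keyed by (chromosome, strand, acceptor, donor) need ≥ 1 surviving
read and genomic span end − start strictly < 100,000 bp. The mismatch
criterion is enforced per read (the stricter reading of "mismatch ≤ 2"),
and each call records the maximum among its surviving reads. Calls are
named circRNA1..n in coordinate order, so they are invariant under
evidence shuffling. Classification: full-exon when both boundaries
coincide (± a configurable tolerance, default 0) with exon boundaries of
one annotated gene and the call lies within that gene's span; exon-intron
when inside a gene otherwise; intergenic when no gene overlaps.

## Differential expression

The study design is two single libraries, so no replicate dispersion can be
estimated; replicate-free designs are typically pushed through a mix of external tools. This
package standardises on one documented exact test, keeping the threshold
logic — which is the procedure that matters — tool-independent:

* `poisson_exact` (default): conditional on a+b, the count a is
  Binomial(a+b, N_a/(N_a+N_b)); two-sided p sums outcomes no more probable
  than observed. Conservative under the null (empirical type-I ≈< 0.05).
* `nb_exact(dispersion)`: the analogous conditional test for two
  negative-binomial counts with a supplied common dispersion; dispersion 0
  reduces to the Poisson test.

Fold changes are computed on depth-normalised abundances (CPM by default,
FPKM with lengths) with a pseudocount of 1, which keeps library-specific
features finite; those features are flagged separately (A_only/B_only on
zero raw counts). Thresholds are applied with the printed comparisons:
strict on |log2FC| (a feature at exactly 2.0 is *not* DE), inclusive on p.
No multiple-testing correction is applied (the thresholds are raw p
values); the emitted p values can be adjusted downstream when a corrected
analysis is wanted.

## cis pairing and network assembly

cis edges join DE lncRNAs to DE coding genes on the same chromosome with an
interval gap ≤ 100,000 bp, inclusive at the boundary (the protocol states
no strict inequality). Distance is measured between nearest interval ends
(overlap → 0) and signed negative when the lncRNA is upstream relative to
the gene's strand; a TSS-anchored mode is not the default because the rule
text speaks of regions "upstream and downstream of coding genes". No
expression-correlation filter is applied.

Network edges are deduplicated (miRNA, partner) pairs restricted to DE
endpoints at build time — site lists stay reusable across threshold
settings. Triads are materialised explicitly; their count equals
Σ_miRNA sponges(m)·targets(m), which the tests verify as a closed form.
Exports (TSV, SIF, GraphML, JSON summary) are lexicographically ordered
and byte-deterministic.

## Synthetic data

`make_scenario` emulates the two-library anther ('Ant') vs vegetative
('Mix') design at desk scale. Defaults: 30 miRNAs of 21 nt; 200 mRNAs of
300 nt with penalty-composed target sites planted in 25 % of them
(penalties 0–6 covering both sides of the cutoff); 20 lncRNAs and 10
circRNAs of 300/150 nt with planted compliant sponge sites, planted rule
violators, and one junction-wrapping circRNA site; Poisson counts
(dispersion configurable) at base means 200–2000 with 30 % of features DE
at |log2FC| = 3; junction-evidence ladders straddling every circRNA filter
boundary; lncRNA placements at gaps of 25/50/100/150 kb from coding genes;
3 chromosomes.

Construction guarantees, enforced by verification-and-resample loops:

* every planted duplex is re-aligned and must realise its requested penalty
  exactly, and the *predictor itself* must report exactly the planted
  window (or nothing, for decoy penalties above the cutoff) on the finished
  transcript — this catches cheaper gapped sub-alignments through repeats;
* mRNA backgrounds are resampled until no accidental window scores within
  0.5 points of the cutoff for any miRNA;
* planted sponge violators are never reportable (a window of exactly miRNA
  length has a unique pairing path, which breaks a rule by construction);
  incidental compliant windows in the background are enumerated into the
  truth table instead of being suppressed, since zero-background ncRNAs of
  realistic length do not exist under these rules;
* planted fold changes are defined on the normalised scale: down-regulated
  features receive proportionally higher baselines so expected library
  totals balance exactly, otherwise normalisation would shift every null
  feature off zero (single-library CPM has no compositional correction).

What the generator does not emulate: realistic base composition (uniform
i.i.d. backgrounds), read-level errors, positional expression biases,
isoform structure within genes, or genome-consistent transcript sequences
(annotation coordinates and transcript sequences are generated
independently; the genome FASTA is background only). Passing tests
therefore demonstrate algorithmic correctness and contract fidelity on
planted structure, not performance on real libraries. The per-scenario seed
and full configuration are recorded in `scenario.json` next to the outputs;
identical seeds give byte-identical files.

Problem sizes in the test suite (oracle checks on hundreds of random
duplexes ≤ 25 nt, sponge windows ≤ 60 nt, scenario of 200 mRNAs / 30
miRNAs) were chosen to exercise every code path at desk scale while the
whole suite stays interactive.

## Known limitations

* The exact conditional test is conservative; with real replicated data a
  dispersion-aware package is preferable. The thresholds, not the test, are
  the contract here.
* Sponge-rule permissiveness means site lists on real transcriptomes will
  be large; the protocol applies no affinity or conservation filter and
  neither does this package.
* Feature counts and network sizes published for real anther/vegetative
  libraries depend on the original sequencing data and external reference
  databases; nothing here claims to reproduce them from synthetic data.
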