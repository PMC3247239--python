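# Methods

This note documents the models, statistics and numerical choices
behind `promoscan`, in the spirit of a methods appendix: what is
computed, under which assumptions, and where the design was genuinely
open.

## Scanning model

A binding site model is a 4×L count matrix.  Column frequencies use a
pseudocount of ε = 0.01 per cell.  The per-position information weight

    Cᵢ = (100 / ln 4) · Σᵦ f(i,b) · ln(4 · f(i,b)),  clipped at 0,

weights the matrix similarity score

    mss(w) = Σᵢ Cᵢ · f(i, wᵢ) / Σᵢ Cᵢ · maxᵦ f(i,b) ∈ [0, 1].

A window is a hit iff the same score restricted to the **core
positions** — the min(4, L) highest-Cᵢ columns, leftmost on ties — is
≥ 0.75 *and* mss reaches the scan threshold.  This is the published
Quandt-style score underlying the widely used commercial scanner; the
vendor's proprietary core definitions and calibrated thresholds are
not public, so absolute threshold values here are not expected to
match the vendor's numerically.  Cores are configurable
(`n_core` in `Pwm.from_counts`).

Both strands are always scanned (the minus strand via the
reverse-complemented matrix, whose core set is the mirror of the
forward core).  `N` and lowercase (soft-masked) bases contribute zero
frequency at their position, which monotonically lowers any window
score covering them; a fully masked site can never re-appear as a hit.

**Thresholds.**  Per matrix, the optimized threshold "opt" is the
smallest value on a 0.01 grid in [0.60, 1.00] at which the background
match rate is ≤ 0.3 per kb (both strands, core-gated); with no
background supplied the default is 0.85.  The relaxed stringency
"opt−0.1" subtracts 0.1, floored at 0.5.  Per-family pruning keeps the
best-scoring hit of every transitive overlap group (ties: longer
matrix, then leftmost, then + strand).

## The three statistical tests

**Binomial vs. preceding region.**  Under the null a site is equally
likely in the L bp before the TSS and the preceding L bp, so the
promoter count k out of n = k + k_ctrl is Binomial(n, ½);
p = P(X ≥ k) is an exact tail sum computed with log-gamma terms and
`logsumexp` (needed because real effect sizes reach p ~ 10⁻⁶⁰, far
below what a normal approximation can represent faithfully).  Rows
with both counts zero are skipped.  Fold is the plain ratio k/k_ctrl
(∞-flagged at zero control count).

**Dinucleotide-shuffle null.**  Each promoter is shuffled by the
Altschul–Erickson Eulerian-path algorithm: first and last characters
fixed, the multiset of adjacent pairs preserved exactly, last-edge
arborescence chosen by rejection sampling, remaining edges permuted.
Runs of masked bases stay in place and the unmasked segments shuffle
independently; when a mask is in force the shuffle is taken of the
*unmasked* sequence and the mask re-applied (shuffle-then-mask), so
control and real data always contain the same scannable positions.
The per-replicate seed derives from `(seed, promoter id, replicate)`,
so any replicate is reproducible in isolation.  The empirical p is the
fraction of B replicate datasets whose pruned family count is ≥ the
observed count ("≥" rather than ">" is the conservative reading; a
`strict` switch gives the other).  p = 0 is reported as "<1/B".
B defaults to 10,000; the validation studies use 1,000.

**Conservation rank test.**  Scores are per-base values in [0, 1] with
semantics 1 − P(neutral evolution); a raw P-value track is transformed
on ingestion.  For one family, scores of bases covered by ≥1 family
site (whole extent, or only the 4 core positions in core mode,
mirrored for minus-strand hits) are pooled across promoters against
all remaining promoter bases, and compared by a one-tailed rank-sum
test: exact enumeration over rank assignments (midranks for ties) when
both groups have ≤ 10 observations, otherwise the normal approximation
with tie and continuity correction.  Missing scores are excluded
pairwise.  A family "passes" conservation when either the whole-site
or the core variant passes — the two variants trade per-base effect
size against sample size, and requiring both would be conservative in
an uncontrolled way.  Out-of-site bases are *not* purged of other
families' sites; only the tested family's own sites define "inside".

**Multiple testing.**  Bonferroni at α/m, m defaulting to the number
of families actually tested (177 in the reference application).  The
three-character report code per family is 'X' (p < α/m), '+'
(p < α), '.' (neither) for binomial, shuffle and conservation in that
order; the legend is this package's convention.

## Masking

The mask is the union of the full extents of *all* (unpruned)
relaxed-stringency sites of the dominant family plus opt-stringency
TATA sites overlapping the inclusive TSS-relative window [−61, −10].
Unpruned extents matter: masking only pruned representatives leaves
flanks of suppressed overlapping sites unmasked, and the dominant
family can re-appear after masking.  With unpruned extents every
potential hit window contains masked (zero-scoring) bases, so a
post-mask re-scan provably finds no sites of the masked family.
Masked positions become 'n' in sequences (coordinates preserved) and
NaN in score tracks, at identical TSS-relative positions in promoters,
preceding regions (same within-array positions, i.e. shifted by −L in
TSS coordinates), shuffled datasets and score tracks.

## Cross-species turnover filter

Sites predicted per species in their own ungapped coordinates are
mapped to alignment columns.  Species s supports a reference site when
some site of s lies within `slide_w` *columns* of it — the
between-interval gap must be ≤ slide_w, with slide_w = 0 demanding
actual overlap.  (Column distance was chosen over ungapped-bp
distance; for the gapless synthetic alignments they coincide.)  The
evidence for a site is the total branch length of the minimal subtree
spanning its supporting species (edges above the MRCA excluded;
singleton → 0); sites below `min_tree_len` (default 0.17, i.e.
conserved beyond the mouse–rat split, with 50 bp slide) are dropped.
Support sets grow with slide_w and the kept-site count is
non-increasing in the tree-length threshold, which the tests assert.

## Promoter dataset construction

Gene domains extend 1 kb downstream of the ORF and upstream to 1 kb
short of the nearest neighboring ORF edge (100 kb cap, clip-to-zero
with a warning below 1 kb).  cDNAs overlapping >1 domain or on the
wrong strand are discarded; per gene, cDNA blocks plus the ORF are
unioned, gaps < 10 bp merged, and genes with a single merged exon, a
pseudogene flag, or an intron entirely downstream of the ORF are
removed; the TSS is the most upstream transcribed boundary.  All
coordinates are 0-based half-open; the TSS is stored as the upstream
transcript boundary so the promoter is [tss − L, tss) on + and
[tss, tss + L) on −, always reported 5'→3' toward the TSS, with
TSS-relative position −1 adjacent to the TSS.

Recent duplicates are pairs with NG86 synonymous divergence
(Jukes–Cantor corrected) < 0.3 — a deliberate, dependency-free
approximation to the ML estimate used with codeml-style tools; the
test suite pins it to an independent codon-counting implementation —
or with a flank alignment of ≥ 200 bp at ≥ 70% identity (12-mer
seeded, ungapped X-drop 20, +1/−1 scoring; a precomputed pair table is
also accepted).  Single-linkage clusters (connected components of the
pair graph) are reduced to one representative chosen by a seeded RNG
(default seed 42) — "arbitrary but reproducible".

## Synthetic data: what it does and does not emulate

The generator draws background from a *first-order* Markov chain with
stationary GC equal to the target (default 0.364, the AT-rich promoter
composition) and mild autocorrelation (persistence ρ = 0.1); planted
site counts are Poisson with positional laws on the site *center*
(defaults: dominant 21-bp motif at 1.4 sites/promoter, Gaussian center
−75 ± 40 bp; TATA-like motif Gaussian −35 ± 12 bp inside the canonical
[−60, −10] band); site sequences are sampled column-wise from the
matrix and spliced on a random strand without overlaps.  Conservation
is iid Beta(2, 5) background plus a +0.4 boost inside planted sites,
clipped to [0, 1].  Cross-species sets lose each site with probability
1 − e^(−λd) (λ default 2.0) and jitter survivors by N(0, 8 bp); the
bundled 4-species tree reproduces the rodent/primate spanning-subtree
scale (mouse–rat 0.161, mouse–human 0.453, mouse–rat–human 0.537).
Duplicate promoters are copies with iid substitutions.

Not emulated: indels and alignment gaps (alignments are gapless),
repeat elements, CpG islands, spatially varying conservation outside
planted sites, and second-order sequence structure.  Passing tests on
this generator therefore demonstrate the statistical machinery —
calibration under a composition-matched null, power against planted
signal, masking correctness, turnover monotonicity — not performance
on any real genome.

## Validation studies and problem sizes

Two study helpers drive the acceptance checks and the results script:

* **Null calibration** — 150 promoters, 50 decoy families, B = 1000,
  no planted motifs: families significant in all three tests at the
  Bonferroni level are counted (expected ≈ 0; the suite allows ≤ 1
  across five seeds).
* **Parameter recovery** — 300 promoters, one planted 21-bp motif at
  1.4 sites/promoter, conservation boost 0.4, B = 1000: the planted
  family must be Bonferroni-significant in all three tests, ≥ 95% of
  decoys must not be, and a post-mask re-scan must find zero
  planted-family sites.

These sizes keep a full run to a few minutes on one core while leaving
the statistical conclusions far from their thresholds (the planted
family's p-values are tens of orders of magnitude below the cutoff).

## Numerical and degenerate-input choices

* Binomial tails in log space (`gammaln` + `logsumexp`); empirical
  p-values live on the grid {0, 1/B, …, 1}.
* Score ties in pruning break deterministically (score, length,
  leftmost, + strand); information ties in core selection break
  leftmost.
* Sequences shorter than 3 are returned unchanged by the shuffle
  (endpoints are fixed, so nothing can move).
* Empty rank-sum groups yield NaN p-values, rendered '.' in reports;
  zero-count families are skipped in enrichment rows.
* Saturated synonymous divergence (Jukes–Cantor argument ≤ 0) yields
  "no estimate" and never flags a pair as similar.
* All generator and pipeline randomness flows from explicit integer
  seeds; shuffle sub-streams are keyed by (seed, promoter, replicate).

## Known limitations

* The similarity score approximates, but is not numerically identical
  to, the commercial scanner's; calibrated "opt" values differ in
  absolute terms.
* NG86 underestimates dS relative to ML codon models at high
  divergence; with the 0.3 cutoff this is benign (the regime of
  interest is low divergence).
* The normal rank-sum approximation loses relative accuracy in the
  extreme tails for small groups (the exact path covers groups ≤ 10).
* GC-matched non-dominant-family promoter controls are deliberately
  not implemented; composition-matched shuffles and the preceding
  regions are the supported nulls.
* Only one masking round is automated; further rounds can be run
  manually by feeding masked FASTA back in.
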