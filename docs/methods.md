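# Methods

This note documents the models and procedures implemented in `mitocompare`,
the defaults and why they were chosen, and what the synthetic data do and do
not establish about real data.

## Coordinate and layout model

Annotations use 1-based inclusive coordinates; a feature wrapping the origin
of a circular genome is written `end < start` and resolved by index
arithmetic modulo the genome length. Feature lengths are always recomputed
from coordinates, never trusted from a printed "size" column — published
annotation tables occasionally disagree with their own coordinates by a
base (the bundled table has two such rows), and coordinates are the
operational truth.

The layout report walks features in table order regardless of strand and
assigns each adjacent pair the signed gap `next.start − prev.end − 1`
(negative = overlap); on a circular genome the last/first pair closes the
circle. The control region is an ordinary feature (`ftype=CR`), so the
layout arithmetic tiles the whole molecule and the identity
`Σ lengths − overlaps + spacers = genome length` is testable.

Light-strand ("L") genes are extracted as the reverse complement of their
heavy-strand coordinates; all per-gene statistics operate on that
coding-strand-oriented sequence, which is why L-strand genes show inverted
composition skews.

## Composition

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), A+T% = 100·(A+T)/(A+C+G+T).
IUPAC ambiguity codes and N are excluded from every numerator and
denominator, so the statistics do not depend on how ambiguity would be
expanded. A zero A+T (or G+C) pool makes the corresponding skew undefined;
it is reported as NaN, never silently as 0. Per-class rows pool raw counts
across the class's genes (arithmetic on merged counts), rather than
averaging per-gene statistics — pooling weights genes by length, which
matches how a single concatenated region would be measured.

## Codon usage

The genetic code is NCBI transl_table 2 (vertebrate mitochondrial), built
from Biopython's table with one presentation change: leucine and serine are
split into their two mitochondrial tRNA families, Leu1 = CUN, Leu2 = UUR,
Ser1 = AGY, Ser2 = UCN (AGA/AGG being stops leaves Ser1 two codons). RSCU
is normalized within these labeled families: RSCU(c) = n_c·k / Σ n, k the
family size, so every observed family sums to k and uniform usage gives 1.
This differs from conventions that treat Leu and Ser as single 6-fold
families; the family-sum invariant is the same, individual Leu/Ser RSCU
values are not directly comparable across the two conventions.

A CDS whose length is not a multiple of 3 carries an incomplete stop; the
trailing 1–2 nucleotides are reported as the markers "T-"/"TA-" (completed
to UAA by polyadenylation in vivo) and never enter codon counts. Codon
totals pool all 13 PCGs per genome and exclude stop codons but include the
start codon; internal stop codons are tolerated with a warning (and
excluded) so a locally perturbed gene cannot poison the pooled table.

## Divergence statistics

All site filtering is **pairwise deletion**: a site is dropped for a pair
exactly when either member carries a non-ACGT symbol there. π is the mean
over unordered pairs of (differences / valid sites). Sliding windows
advance `[s, s+window)` by `step` (defaults 500/100 bp); a final partial
window is retained and flagged. For clade-level profiles the windows run
over the concatenated gene set in genome order.

K2P: with transition proportion P and transversion proportion Q,
d = −½ ln(1−2P−Q) − ¼ ln(1−2Q). A non-positive log argument is reported as
an explicit saturation flag with d = NaN; saturated pairs are excluded from
gene means with a warning. Per-gene "overall mean distance" is the
arithmetic mean of d over unordered pairs.

Ka/Ks is Nei–Gojobori (1986): potential synonymous sites are fractional per
codon position (mutations to stop codons are eliminated from consideration,
keeping 3 sites per codon), averaged over the two sequences; observed
differences in multi-hit codons are averaged over all minimal substitution
pathways, with pathways passing through stop codons excluded and the rest
re-weighted equally (if every pathway is blocked — a degenerate corner —
all are used and a warning is emitted); pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected, d = −¾ ln(1 − 4p/3). Conventions: Ka = 0 gives
ratio 0; Ks = 0 with Ka > 0 leaves the ratio flagged undefined, never
infinite; p ≥ 3/4 flags the correction as saturated. Clade-level per-gene
Ka/Ks averages the site and difference counts across pairs before
correcting. NG86 is a counting estimator: on data simulated with a given ω
it recovers the ordering of ω across genes reliably, the absolute value
only approximately (it ignores the transition/transversion bias in the
mutation process).

## Phylogeny

Neighbor joining (Saitou & Nei) on the K2P matrix of the concatenated
13-PCG + 2-rRNA set. Ties in the Q-criterion are broken deterministically
(lexicographically smallest index pair), so trees are byte-reproducible;
negative branch lengths are clamped to zero with the total deficit recorded
on the tree (it is exactly 0 on additive inputs, which the property suite
checks for 4–12 leaves). The tree is unrooted (trifurcating root);
outgroup rooting is a presentation-only rotation. Bootstrap support
resamples alignment columns with replacement, rebuilds NJ per replicate,
and reports the percentage of replicates containing each internal
bipartition of the full-data tree; replicates with saturated pairs are
dropped and the effective count reported, and an alignment with no
variation leaves supports undefined rather than confidently arbitrary.
NJ + bootstrap is a desk-scale distance method; it is not a substitute for
Bayesian or maximum-likelihood inference on large taxon sets, and no claim
beyond the small-clade topology is attached to it.

## Synthetic clade generator

The generator emulates a shallow 4-taxon clade of ~16.6 kb circular
mitogenomes on the bundled annotation layout.

* **Ancestor.** A random sequence at the target composition
  (A,C,G,T) = (0.2969, 0.3272, 0.1533, 0.2226) — solved from A+T = 51.95 %,
  AT-skew 0.143, GC-skew −0.362 — is rewritten so every PCG carries its
  template start codon, no in-frame internal stops, and its template
  (possibly incomplete) stop. Genes overlap in two reading frames at once;
  constraints are reconciled by iterated stochastic repair until all hold
  simultaneously, which converges because real mitogenome overlaps always
  leave each violated codon a free base. A PCG whose coordinate-derived
  length is not a multiple of 3 gets the incomplete stop its length implies,
  even where the source table printed a full one (one such gene, ND3, in
  the default template).
* **Nucleotide process.** Sites evolve independently under K2P with
  transition/transversion rate ratio κ = 8 (mitochondrial sequences are
  strongly transition-biased); each branch draws per-site states from the
  exact K80 transition matrix, so realized divergence is unbiased at any
  branch length. No rate variation across sites within a gene (no Γ) and no
  indels — alignments are gapless by construction, which is a deliberate
  simplification: alignment itself is out of scope.
* **Codon process.** PCGs receive K2P proposals at intensity d per site;
  synonymous proposals always fix, amino-acid-changing proposals fix with
  probability ω, stop-creating proposals never. Synonymous-site divergence
  therefore tracks d, and the realized nucleotide divergence is
  d × acceptance, where the acceptance fraction (~0.31–0.37 under the
  default ω map and κ) is computed analytically by `expected_acceptance`
  and folded into the truth file. Start codons may only toggle within
  {ATG, GTG}, terminal stops within the stop set, and incomplete-stop tails
  are held fixed. After each branch, the ancestor's repair pass re-runs so
  the overlap zones cannot leave a neighbor's frame broken (it touches at
  most a few bases per branch).
* **Defaults as study conditions.** The guide tree
  `((americana:0.012,ferina:0.012):0.006,(fuligula:0.016,baeri:0.020):0.006)`
  gives a mean pairwise path of ~0.038 substitutions/site with a deep
  internal split. Per-gene proposal multipliers are set so realized π spans
  ~0.01 (rRNAs, ATP8) to ~0.07–0.08 (ND3, ND4L, control region), and the ω
  map spans 0.01 (COII, strongest constraint) to 0.105 (ATP8, weakest) —
  the pattern of rate and constraint heterogeneity reported for
  mitochondrial PCGs in shallow waterfowl clades. tRNAs default to
  multiplier 0.4.
* **Determinism.** All randomness flows through one seeded numpy Generator;
  a (seed, config) pair reproduces the dataset byte for byte.

**What passing tests show — and don't.** Recovery of the guide tree, of
per-gene K2P within 3 binomial SE of truth, and of the ω ranking
demonstrates that the estimators are correctly implemented and internally
consistent under their own model assumptions. Real mitogenomes violate
those assumptions (rate variation across sites, compositional
non-stationarity, indels, sequencing/annotation error), so simulated
recovery does not by itself certify accuracy on real data; the
published-value reproduction test against the four deposited GenBank
records exists for that purpose and requires those records locally.

## Numerical choices and degenerate inputs

* Undefined quantities are explicit: NaN + flag for saturated distances and
  correction overflows, undefined-flag for Ka/Ks with Ks = 0, NaN skews for
  empty base pools. Nothing degenerates silently to 0.
* π over a window with no valid sites is NaN; a pair with no valid sites is
  skipped from π with a warning.
* K2P variance for the 3-SE checks uses the standard delta-method formula
  with coefficients 1/(1−2P−Q) and ½[1/(1−2P−Q) + 1/(1−2Q)].
* Percentages are rounded to 2 decimals and skews to 3 in reports; full
  precision is kept internally.
* Problem sizes: the default clade (4 × 16.6 kb), 100–1000 bootstrap
  replicates, and 5–20 kb simulated sequences in the calibration tests keep
  the full suite and the acceptance script in the seconds-to-a-minute
  range on one CPU.

## Known limitations

* NG86 Ka/Ks, not ML (codeml-style) ω estimation; printed third decimals of
  counting-based tools may differ by implementation detail, so published
  comparisons use a ±0.01 tolerance.
* NJ/K2P phylogeny only; no model selection, no Bayesian/ML tree search.
* The annotation reader maps common GenBank gene/product spellings to
  canonical names but is not a general-purpose synonym resolver.
* The simulator's per-gene truth for PCGs is the analytic
  proposal-acceptance approximation; it ignores second-order effects
  (composition drift at synonymous sites along a branch), which are well
  inside the binomial noise at these divergences.
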