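# Methods

This note documents the models and procedures `mitocup` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates, strands and regions

All internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive locations (including `join(x..L, 1..y)`
origin-spanning features) are converted at the I/O boundary.  Strands are
labelled J (majority, `+`) and N (minority, `-`).  Gene names are
normalized to canonical symbols through an alias table because public
mitogenome annotations are heterogeneous (ND1/NADH1 → nad1, COI → cox1,
16S → rrnL, D-loop → CR, tRNA-Ser(UCN) → trnS2, …); serine/leucine
isoacceptors are disambiguated by recognized codons or anticodon when the
label carries them, defaulting to the first copy otherwise.

Boundary elements are computed by interval arithmetic after unrolling the
circle: for each adjacent feature pair, a positive gap is an intergenic
spacer (IGS), a negative gap an overlap (OL), and an exact abutment yields
no element.  A feature nested inside its neighbour is reported as an OL of
the shorter feature's length, with a warning — annotation of this case is
not standardized and callers should inspect it.  Opposite-strand overlaps
are treated like same-strand ones (the classic trnW/trnC overlap is
opposite-strand).  The "IGS total" convention excludes the control region
and the boundaries flanking it (`exclude_cr=True` by default).

## Composition

Skews follow AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C).  IUPAC
ambiguity codes are excluded from both numerator and denominator of every
fraction, so skews remain well defined; a zero denominator reports NaN.
Strand-specific rows use reading-direction sequences (reverse complement
for N-strand genes), which is why the two strands show opposite GC-skew
signs.  Reported rounding follows the field's tables: percentages to two
decimals, skews to three.

## Codon usage (translation table 5)

The family structure of the invertebrate mitochondrial code is taken from
Biopython's table 5 and grouped into synonymous families: 12 two-fold,
6 four-fold, one six-fold (Leu) and one eight-fold (Ser = TCN + AGN)
family; 62 sense codons; stops TAA/TAG.  Counting is by consecutive
non-overlapping triplets with trailing partial codons (incomplete stops, a
single T completed by polyadenylation in vivo) dropped, start codons
counted as written, and stop codons excluded unless requested.  A
genome-level "total codon" count uses the concatenated PCG length divided
by three, the convention used in comparison tables (per-gene complete
triplets give a slightly smaller number because of incomplete stops).

RSCU is a codon's count divided by its family's mean count; family sums
equal family sizes whenever the amino acid occurs.

ENc is Σ_k K_k / F̄_k over degeneracy classes with K = {12, 6, 1, 1} for
sizes {2, 4, 6, 8}, so the theoretical range under table 5 is [20, 62]
(not the familiar 20–61 of the standard code, which has two single-codon
amino acids).  Values are reported unclamped.  Two homozygosity estimators
are offered:

- `wright`: the plug-in F = Σ p_i² per family, class-averaged.  The
  plug-in form (rather than the (nF−1)/(n−1) small-sample correction) is
  used deliberately so ENc stays inside [20, 62] and equals exactly 62
  under uniform usage and 20 under one-codon-per-family usage.  Families
  with n < 2 carry no information and take their class mean; a wholly
  absent class is rescaled out by extrapolating the observed classes to
  the full codon complement.
- `sun2012`: the pseudocount estimator F_j = Σ_i ((n_ij+1)/(n_j+m_j))²
  with codon-count-weighted class averages — defined for every gene, and
  the preferred estimator for short genes with rare amino acids.

The two agree within ~1 ENc unit for n ≥ 1000 codons.  A `split_families`
switch treats the 6- and 8-fold families as 2+4 / 4+4 for sensitivity
checks against tools that split by the first two codon bases.

GC3s is the G/C fraction at third positions of synonymous sense codons;
under table 5 every sense codon is synonymous, so GC3s = GC3 over sense
codons (the operation stays distinct for generality across codes).

## Selection analyses

The ENc-plot compares observed ENc with the composition-only expectation
ENc = 2 + s + 29/(s² + (1−s)²) at s = GC3s.  Since qualitative readings
("on/above/below the curve") need a band, points within ±1 ENc unit of the
curve are classified "on"; the signed residual is always reported.

The neutrality plot regresses GC12 on GC3 by unweighted OLS across the
species panel, per gene.  M = 100·slope is read as the mutational-pressure
percentage and N = 100 − M as selection/constraint; M + N = 100 by
construction and M is flagged when outside [0, 100].  Slopes are invariant
to whether GC values are fractions or percentages; intercepts are not, so
the scale is an explicit option in the CLI.

RSCU matrices (species × 62 sense codons, NaN → 0 for absent amino acids)
are decomposed by eigendecomposition of either the covariance or the
correlation matrix; both are offered because AT-rich panels have wildly
unequal codon variances.

## Divergence (NG86)

Synonymous site counts per codon use the fraction of synonymous changes
among the possible single-base changes at each position, excluding changes
to stop codons from both numerator and denominator, so S + N = 3 × codons
exactly.  Observed differences between codon pairs are averaged with equal
weights over all orderings of the differing positions; pathways through a
stop codon are excluded, falling back to all pathways when every one is
blocked.  Proportions are Jukes–Cantor corrected; the correction is
undefined at p ≥ 3/4 and reported NaN, and ω is NaN (not 0 or a floor
value) when dS = 0.  Codons containing gaps or ambiguity codes in either
sequence are excluded pairwise.  Per-species panel summaries (adS, adN)
aggregate a species' pairwise values by mean (median available).

This counting estimator is a transparent, assumption-light measure of
dS/dN; maximum-likelihood codon models (branch models, F3X4 frequencies,
likelihood-ratio tests) are intentionally out of scope, and externally
computed dS/dN tables can be supplied to the regression stage as TSV.

## Regression suite

Rows are filtered by a response-outlier rule (beyond 3×IQR from the
quartiles — "a few extreme outliers" needs a concrete rule, and 3×IQR
removes only egregious points), then split 75/25 with a seeded shuffle
(default seed 12345, configurable).  Model classes:

- LM: ordinary least squares.
- PM: polynomial least squares with the degree minimizing AIC (or BIC)
  over 1..20.  Fitting uses a Legendre basis on the predictor rescaled to
  [−1, 1]; raw power bases are numerically unusable at degree ~20.
  A forced degree of 1 reproduces the LM fit.
- AM: penalized B-spline additive smoother (statsmodels GLMGam, Gaussian
  family, identity link, basis df = 10 capped at n/3), with the penalty
  weight chosen by the fitter's generalized cross-validation-style
  criterion, and the effective degrees of freedom (edf) reported.  The
  additive model is specified behaviorally — any penalized smoother with
  GCV-style smoothness selection qualifies — so edf values are not
  comparable across basis implementations.

Every fit reports R², adjusted R², AIC, held-out RMSE, and residual
diagnostics: Breusch–Pagan for heteroscedasticity, Shapiro–Wilk for
normality, plus plot-ready residual-vs-fitted and quantile–quantile
vectors.  Natural-log response transforms drop non-positive rows and
report the count.

## Synthetic data generator

The generator is the package's test bed and defines its reference study
conditions.  Defaults realize the published annotation structure of the
*Blepharipa* sp. (Muga uzifly) mitogenome: 15,080 bp, 37 genes in the
ancestral dipteran arrangement (9 J + 4 N PCGs totalling 11,166 nt =
3,722 codons; 22 tRNAs, 1,466 nt; two rRNAs, 2,143 nt), a 168 bp control
region, ten overlaps totalling 35 bp (max 8 bp at trnW/trnC), and fifteen
spacers totalling 139 bp (max 40 bp at trnE–trnF).  The four major spacers
and three major overlaps are fixed from the published record; the eleven
minor spacers (sum 49 bp, each < 10 bp) and seven minor overlaps (sum
13 bp) are a fixed concrete choice consistent with those totals, and 33 nt
sit in the two control-region-flanking gaps, which the spacer total
excludes.  Incomplete stops (single T) are placed on cox1/cox2/nad4;
cox1 starts TCG and nad1 TTG, the others ATN.

PCG sequences are sampled codon-by-codon i.i.d. from a per-gene
distribution built from amino-acid frequencies and within-family codon
weights, constrained so the expected third-position A/T fraction equals
the `at3_target` exactly (default 0.9207).  The frequencies and weights
were calibrated once so the default gene pool reproduces the reference
regime: PCG A+T ≈ 77.3%, RSCU(TCT) ≈ 2.7 with TCT ≈ 4.4% of sense codons,
reading-direction J-strand genes T- and C-skewed and N-strand genes T- and
G-skewed (the canonical mitochondrial strand asymmetry, via a G-tilted
N-strand profile).  tRNA/rRNA/spacer sequences are random with target AT
fractions; the control region carries 15 nt poly-T and poly-A runs around
an AT-rich core.  Features that overlap share bases, with the downstream
feature's sequence taking precedence — overlapped gene termini are
therefore rewritten by their neighbour, as in real overlapping genes.

What the generator does *not* emulate: codon autocorrelation along genes,
tRNA/rRNA secondary structure, repeat architecture of the control region,
indels, and between-gene amino-acid composition differences beyond the
strand split.  Tests passing on this material therefore validate the
arithmetic of the statistics and the pipeline's bookkeeping on realistic
composition — not annotation quality or alignment handling on real
records, which enter through the GenBank reader's normalization layer.

`diverge_pair` copies a genome applying substitutions at NG86-classified
synonymous/nonsynonymous positions at planned proportions of the
respective site totals (single-hit regime, at most one substitution per
codon; stop codons never created; overlap-shared codons skipped so the
substitution ledger equals the Hamming distance).  The `at_bias` parameter
models directional mutation pressure by up-weighting A/T replacement
bases; at the default 0.5 the process is base-neutral, while panel
generation uses 0.85 so that repeated divergence does not erode the AT3
gradient — without it, synonymous changes drift composition toward G/C
and wash out the composition–divergence relationship the panel is built
to exhibit.

`generate_divergence_panel` derives a species panel from one ancestor
with two built-in gradients chosen to mirror the comparative regime under
study: longer genes carry higher AT3 targets (0.86–0.97), and per-gene
synonymous divergence grows with AT3 (0.03–0.14 per species, scaled by a
random per-species factor in [0.5, 1.5]), with nonsynonymous divergence at
ω = 0.08 of synonymous (strong purifying selection).  Consequently the
panel shows ENc falling with gene length and adS falling with GC3s, and
those are the signs the acceptance run reports.

## Problem sizes and seeds

The test suite and the acceptance script run entirely on generated data:
one reference-condition genome (15 kb), species panels of 6–8 genomes,
10,000-codon genes for AT3 recovery, 1,000-replicate Breusch–Pagan null
calibration at n = 120, and the full 62×62 codon-pair grid for the
divergence oracle.  These sizes give sampling errors comfortably inside
the tolerances asserted while keeping a full run to a few seconds.  All
randomness flows through explicit integer seeds; identical seeds give
byte-identical outputs, including GenBank and TSV files written by the
CLI.

## Known limitations

- The GenBank reader's control-region fallback (largest unannotated gap
  adjacent to rrnS) is a heuristic; records with unannotated duplicated
  control regions will confuse it, and the parser deliberately reports
  what the file says rather than curating known annotation errors.
- NG86 with Jukes–Cantor correction saturates near p = 3/4 and reports
  NaN there; deep divergences need the ML machinery this package
  deliberately omits.
- ENc values from the two estimators differ systematically for short
  genes (the plug-in overstates bias for rare amino acids); cross-tool
  comparisons should fix the estimator.
- The additive model's edf depends on the spline basis and penalty
  implementation and should not be compared across packages.
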