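# Methods

## Model

For one TF, every genomic occurrence of its core motif is an example.  The
response is the normalized ampDAP-seq peak height (0–1000 affinity units;
0 for occurrences not under a peak), taken as a proxy for in-vitro binding
affinity.  The predictors are the 13 DNA shape parameters — MGW; the
intra-base-pair parameters shear, stretch, stagger, buckle, propeller
twist, opening; the inter-base-pair step parameters shift, slide, rise,
tilt, roll, helix twist — at every position of the motif core and of a
flanking border of `b` bases on each side (default `b = 4`; features are
precomputed for the ±32-base window so any `b ≤ 32` trains by column
selection).  Shape values come from a pentamer lookup table: position `i`
receives the table row of the pentamer centered on `i`, so a window of
length L yields L − 4 feature positions.  All 13 features, including the
step parameters, are indexed by single positions.

A random-forest regressor is fit with per-site weights (bound sites are
up-weighted by the unbound:bound ratio) under mean-squared-error loss.
Ranking quality of bound vs unbound on a held-out validation split is
summarized by the area under the precision–recall curve, compared against
ranking the same sites by their motif log-odds score ("motif-only"
baseline).

### Strand canonicalization

Minus-strand hits are reverse complemented before featurization, so the
shape matrix always reads in the motif's 5′→3′ orientation.  When a
collapsed (512-row) query table is expanded, the reverse-complement
pentamer copies even-symmetry features and flips the sign of shear,
buckle, shift and tilt — the standard base-pair/step parameter sign
conventions.  The featurizer itself never needs those rules (it always
looks up the canonicalized window), but the loader and a property test
enforce them.

### Degenerate inputs

Hits whose `(b + 2)`-extended window crosses a contig end or contains an
ambiguity code are discarded, not padded.  A peak file without summit
offsets falls back to interval midpoints with a warning.  If all bound
signals are equal, min–max normalization maps them all to 1000.  A dataset
with no bound sites aborts the pipeline.

## Motif scanning

MEME minimal files are parsed (per-cell pseudocount 0.1, then row
renormalization; the file's stated background, uniform if absent) and
scored as log-odds in bits.  Exact p-values use the standard
dynamic-programming convolution of the per-position score distribution
under the background model, on a score grid of 10⁻³ bits (configurable);
p-values are exact for the quantized score, i.e. within one grid step of
the continuous value.  Zero-probability cells are floored at −30 bits per
position so the grid stays bounded; any such window scores far below every
practical threshold.  Both strands are scanned; when both orientations of
the same interval pass the threshold only the better-scoring one is kept
(ties → plus), so palindromes count once.  The scanner keeps every hit
(there is no stored-score memory cap).  P-values for minus-strand windows
use the plus-orientation score distribution, which is exact for
complement-symmetric backgrounds (the default uniform background
included).

## Dataset rules

* FRiP filter: strictly greater than 5 %.
* Artifact filter: a target peak recurring (summit-to-summit distance
  ≤ 100 bp, same contig) in more than ⅓ of all datasets — counting the
  target itself — is discarded.  With fewer than 3 datasets the filter is
  skipped (any peak would trivially exceed ⅓).  The threshold is a
  parameter.
* Binding label: a motif occurrence is bound iff some peak summit lies
  within 80 bp of any base of the motif interval; among several, the
  highest-signal peak wins.
* Homodimer rule: if bound peaks with ≥ 2 in-radius occurrences outnumber
  single-occurrence peaks, the TF is treated as a homodimer binder and
  single-occurrence bound hits are dropped; otherwise (ties included) the
  multi-occurrence bound hits are dropped.  Unbound occurrences are never
  affected.  Each retained occurrence remains an independent training
  example carrying its peak's signal.
* Balancing: unbound sites are subsampled (seeded, uniform) to at most
  5 × bound; if the total would still exceed 120,000, to 3 × bound.  Bound
  sites are never removed.
* Sample weights are computed after balancing: bound = unbound/bound,
  unbound = 1.
* Split: seeded 80/20 stratified on the bound flag; the validation split
  is used only for evaluation, never for model selection.  Retraining on
  the training split alone reproduces the published predictor exactly,
  which the test suite uses as the selection-hygiene check.

## Training

Randomized search draws parameter combinations uniformly **without
replacement** (duplicates re-drawn; draws capped at the size of the finite
space) from `n_estimators` ∈ [10, 200], `max_features` ∈ {all, sqrt,
log2} and `max_depth` ∈ [4, 12].  "all" is the historical regression
meaning of "auto" (every feature considered at each split).  Each
candidate is scored by k-fold (default 5) cross-validated weighted MSE on
the training split; the winner is refit on the whole training split.  All
randomness is seeded; fixed seeds give identical chosen parameters and
predictions.

AUPRC uses the average-precision convention Σ precision·Δrecall (step
interpolation, ties grouped at one threshold), not the trapezoid — the two
differ on coarse curves, so the choice is fixed and tested against a
brute-force confusion-matrix sweep and sklearn's `average_precision_score`.

## Shapley attribution

Interventional (background-conditional) Shapley values are computed
exactly.  For each leaf of each tree, the path's splits are consolidated
into one interval per feature; for an explained sample x and a background
sample z, the leaf is reached under coalition S iff S contains every
feature whose interval only x satisfies (set A, size a) and excludes every
feature only z satisfies (set B, size b).  The Shapley value of that
reachability game is closed-form: features in A receive
`v·(a−1)!·b!/(a+b)!`, features in B receive `−v·a!·(b−1)!/(a+b)!`.
Summing over leaves, averaging over the background set (default 100
seeded training sites) and over trees gives attributions satisfying local
accuracy (base value + Σ contributions = prediction) to floating-point
precision; the test suite verifies exact agreement with 2^M subset
enumeration.  Ranking ties are broken by canonical (position, feature)
order.  In category summaries MGW is reported as its own class and
excluded from the intra/inter split, since it is not a base-pair/step
parameter.

## Sequence design

Candidates are unique random sequences of length 18 with the core motif
centered (offset ⌊(18 − m)/2⌋), rejected if they occur in the genome on
either strand (checked against a k-mer index of both strands).  Their own
bases provide the pentamer context, which requires
length ≥ m + 2·(b + 2).  The most extreme `per_class` candidates with
predictions above 150 / below 15 affinity units form the high/low sets;
classes that cannot be filled return what exists with a warning.

## Synthetic studies

The generator emulates the inputs the trainer expects from real data:

* a multi-contig genome (default 1 Mb nuclear + `ChrC`/`ChrM` organelle
  contigs, GC 0.36, i.i.d. bases);
* 1,000 planted instances of a 6-bp consensus (`TTGACC`), random strand,
  placed on a jittered grid so loci are > 180 bp apart, never overlap, and
  always admit the ±32-base window and a 200-bp peak;
* true affinity `clip(a₀ + Σⱼ wⱼ·zⱼ + ε, 0, 1000)` with a₀ = 400, two
  causal features `roll@-1` (+300 units/SD) and `MGW@+2` (−250 units/SD)
  standardized over loci, ε ~ N(0, 50); bound iff affinity > 500 — about
  40 % of planted loci;
* a target narrowPeak dataset (one 200-bp peak per bound nuclear locus,
  summit at the motif midpoint, signal = true affinity), 30 artifact
  peaks shared by **all** pseudo-datasets at motif-free positions, and 4
  further datasets with their own decoy peaks drawn from a disjoint
  motif-free pool (so decoys never collide with true peaks and the
  artifact filter's effect is exactly the artifact set); one dataset
  carries FRiP 0.04 to exercise the FRiP cut;
* a random 1024-pentamer shape table symmetrized to the sign rules, with
  loosely realistic ranges (MGW ≈ 3–7 Å, angles tens of degrees).  It is
  synthetic: values carry no biophysical meaning.

What this does **not** emulate: real pentamer shape values, sequence
composition bias, peak-width variation, read-level noise, correlated
motif families, or methylation effects.  Passing recovery tests therefore
shows that the pipeline identifies shape-affinity relationships it is
pointed at, not that any particular biological TF behaves this way.

### Problem sizes

Simulated replicate studies (tests, acceptance script) use the default
1-Mb study with a reduced randomized search — 8 draws over
`n_estimators` ∈ [20, 80], `max_depth` ∈ [4, 8], 3-fold CV — which keeps a
full replicate under ~20 s while leaving the search space genuinely
random.  The 75 × 5-fold search remains the default for real datasets.
Attribution in replicate runs uses 40 validation samples against 50
training-site backgrounds; Shapley values are exact regardless of these
counts, which only set the averaging population.

## Known limitations

* The exact-p-value DP assumes position independence of the background
  (order-0), like the scanner it mirrors.
* Interventional Shapley cost grows with leaves × background × samples;
  for very deep forests use modest background sizes.
* The homodimer rule trains on occurrences, not joint pair windows; no
  pair-spacing feature is constructed.
* Motif discovery is out of scope: the package consumes MEME-format
  motifs produced elsewhere.
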