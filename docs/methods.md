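# Methods

`tfannot` implements a four-step workflow for annotating transcription
factors (TFs) from amino-acid sequence alone: TF identification, structural
superclass assignment, DNA-binding-domain (DBD) localization, and DNA-motif
inference by similarity-driven transfer of position frequency matrices
(PFMs). This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Homology features (steps 1–2)

Queries are compared to a labeled protein database by optimal local
alignment (Smith–Waterman, BLOSUM62, affine gaps costing `open + g·extend`
with open 11, extend 1 — the common protein-search defaults). Raw scores S
are converted to bit scores `(λS − ln K)/ln 2` with the published gapped
BLOSUM62/(11,1) constants λ = 0.267, K = 0.041; both are configurable in
`ScoringScheme` because the appropriate Karlin–Altschul pair depends on the
gap model. Alignment is exhaustive rather than heuristically seeded: at
package scale (thousands of sequences) the exact dynamic program is fast
enough, and exactness makes the search oracle-checkable. One hit is kept
per subject (the optimal alignment); no HSP tiling; e-values are not
computed — all downstream filtering is by bit score.

The *bit-score percentile features* summarize the hit list per class: for
each class (TF/non-TF, or each of the five superclasses) the minimum, lower
quartile, median, upper quartile and maximum of that class's hit bit
scores, concatenated in fixed class order (10 dims for the binary task, 25
for superclasses). Quantiles use linear interpolation between order
statistics ("type 7"); this matters for small hit lists and is therefore
pinned and tested. A class with no hits above the threshold contributes a
zero block and is flagged in metadata rather than given extra dimensions.
The default hit threshold is 15 bits.

Comparison encodings implemented alongside: PSSM profile features (an
n×20 log-odds profile from the query plus hit-aligned residues with
background pseudocounts, compressed to 20×20 by summing rows of equal query
residue, divided by sequence length, passed through the sigmoid
`1/(1+e^{−x})`, flattened to 400 values; single-pass profile, no iterative
refinement), k-mer counts (20^k, default k = 2 so the dimensionality is
comparable to the PSSM vector), pseudo amino-acid composition (relative
frequencies plus λ sequence-order correlation factors; Θ is the mean
squared difference of hydrophobicity, hydrophilicity and side-chain mass,
each standardized over the 20 residues; defaults λ = 4, weight w = 0.05 —
with λ = 0 the vector reduces exactly to the composition), and binary
functional-domain composition over the training vocabulary.

## Classifiers

Five base learner families sit behind one interface: SVM (RBF and linear),
k-nearest-neighbours, Gaussian naive Bayes, decision tree, random forest.
Multiclass superclass prediction offers one-versus-rest and the exhaustive
error-correcting output code (ECOC). The exhaustive code for k classes has
2^(k−1) − 1 columns: the first class's row is all ones and the remaining
rows enumerate the binary representations of 0 … 2^(k−1) − 2. Decoding is
by minimum Hamming distance of the concatenated binary predictions to the
class codewords; ties share probability equally (an all-zeros prediction is
decoded like any other bit string). The five-class instance has a minimum
pairwise row distance of 8, i.e. up to 3 base-classifier errors are
corrected.

Evaluation uses stratified 4×4 nested cross-validation: hyperparameters
(SVM C ∈ {0.1, 1, 10, 100}, RBF γ ∈ {1e−3 … 1}; KNN k ∈ {1, 3, 5, 7};
forest size ∈ {100, 500}) are chosen on inner folds only, the winner is
refit on the outer-training split and scored on the held-out fold. The
summary statistic avgROC is the unweighted mean of fold AUCs (and of
one-versus-rest AUCs for multiclass). Fold-wise ROC curves are averaged at
pooled score thresholds (each curve evaluated by step interpolation on its
own threshold list); interpolation at fixed FPR would be the alternative —
pooled-threshold averaging was chosen and is what the averaging tests pin
down.

## DNA-binding domains (step 3)

Domain-scan results arrive as TSV rows with GO annotations. A domain is a
DBD iff its GO set intersects the subtree of the molecular function
"DNA binding" (GO:0003677): the root plus all transitive `is_a`
descendants (`part_of` optional, off by default, matching common
molecular-function subtree practice). Overlapping DBD annotations on one
protein are merged into maximal intervals so duplicated segments cannot
double-weight residues in motif inference. A separate post-filter for
building non-TF training sets removes candidates present in TF databases or
annotated with GO:0003700 (sequence-specific DNA-binding TF activity).

## Motif transfer (step 4)

### Smax log-odds PFM similarity

A *hit* of PFM X is a window whose summed log2-odds score against an iid
background clears a per-PFM threshold: the smallest achievable window score
whose exceedance probability is ≤ α_hit (default 0.01), with α the exact
exceedance at that threshold. 0.01 balances sensitivity against chance
co-occurrence for typical motif widths of 6–12; for uninformative matrices
no achievable score is that rare and the PFM is treated as having no hits.
A pseudocount of 0.01 is added to probability columns before the log-odds
(avoiding −∞); log base 2 throughout.

γ_{X,Y}(k) is the probability that a hit of X at position 0 and a hit of Y
at offset k co-occur in random DNA. It is computed exactly by
factorization: positions covered by only one window contribute independent
score tails; shared positions are enumerated jointly. Scores are quantized
to integer units of 1e−6 bits so distributions convolve in exact integer
arithmetic and the tests can compare against brute-force enumeration with
zero tolerance. When a distribution's support outgrows 2^16 values (only
reachable for long profiles such as merged consensus matrices with
overhangs) it is re-quantized to a coarser grid — a documented
approximation that never affects ordinary motif widths.

s(k) = log2(γ_{X,Y}(k)/(α_X α_Y)); Smax maximizes s(k) over all overlap
offsets, both motif orders and all strand-orientation combinations (using
reverse complements). The normalized similarity is
`smax(X,Y)/√(smax(X,X)·smax(Y,Y))`, clipped below at 0 (anti-correlated
motifs), and the distance is `min(1, max(0, 1 − s_norm))` — a symmetric
premetric on [0, 1] that is invariant under reverse complementation of
either argument. Pairs with γ = 0 at every offset get distance 1.

### DBD similarity features and SVR

Four features describe a DBD pair: global-alignment identity; local
alignment score normalized by `√(s(a,a)·s(b,b))`; a (k,m) = (3,1) mismatch
string kernel computed by explicit neighborhood counting; and the local
alignment kernel (β = 0.5, the β-weighted sum over all local alignments,
whose log/β approaches the optimal local score as β grows), both kernels
self-normalized into [0, 1]. Secondary-structure similarity is not
included: the feature set is purely sequence-derived.

Per superclass, an ε-SVR (RBF, ε = 0.01, C and γ tuned by inner CV) is
trained on within-superclass TF pairs whose normalized local-alignment
similarity exceeds 0.3, regressing the observed normalized Smax similarity
of their PFMs; classes with fewer than 20 eligible pairs fall back to one
model pooled across superclasses. Reported recovery statistics are
computed over the same filter-passing pairs the models are trained to
describe; below that similarity the DBD carries essentially no motif
information and the regression rightly predicts the base rate.

### Transfer, filtering, merging

For a query DBD the same-superclass training factors are scored by the
SVR. The best-match threshold (BMT) is either static or dynamic: the
largest value in [0.5, 0.95] still admitting at least one candidate, i.e.
`min(best predicted similarity, 0.95)`; if nothing reaches 0.5 the outcome
is an explicit no-prediction (not an error). The prediction confidence is
the mean predicted similarity of the selected matches (mean rather than
max: it reflects the homogeneity of everything that is merged).

The selected PFMs pass a single-pass outlier filter: each matrix's mean
Smax distance to the others is compared with τ (default 1.5) times the
grand mean of those values; offenders are dropped, the boundary counts as
out (saturated distances capped at 1 can land exactly on it), and the last
matrix is never removed. Survivors are merged progressively along a UPGMA
guide tree on pairwise Smax distances: at each node the two child profiles
are aligned by ungapped sliding offset over both orientations, maximizing
the summed Pearson correlation of overlapping probability columns
(zero-variance columns score 0); aligned columns are averaged weighted by
the number of contributing source matrices, overhangs are kept, and
columns renormalized. Gapped profile alignment and alternative tree
methods are out of scope.

## Synthetic data

The generator emulates the statistical structure each stage relies on — it
is the package's test bed, not a biological simulator. TF families share a
DBD consensus embedded between flanks drawn from the BLOSUM62 background
composition (so alignment score distributions are realistic); members
substitute each DBD site independently with probability `divergence`
(default 0.2). Family consensi diverge from a superclass-specific core at
rate 0.35, well above the within-family rate, so DBD similarity cleanly
ranks within-family above cross-family pairs. Each member's PFM is the
family's seed PFM (columns concentrated on a random 8-mer consensus,
concentration 20) mixed per column with a symmetric Dirichlet draw at
weight `min(0.9, 2.5 × realized divergence)` — making PFM distance a noisy
increasing function of DBD divergence, the monotone structure the SVR
stage assumes. Motif width 8 keeps the exact Smax computations fast.
Non-TFs are background-composition random sequences; a configurable decoy
fraction (default 10%) carries a mutated TF DBD copy plus a DNA-binding GO
annotation, reproducing the structural ambiguity of domain types shared
between TFs and non-TF DNA binders.

What passing tests show: the pipeline's machinery is correct and its
statistical behavior (near-perfect separability without decoys, monotone
transfer trade-offs, recoverable similarity structure) matches the design
assumptions. What they do not show: performance on real proteomes, where
homology structure, domain architecture and motif families are far messier
than the generator's clean family structure.

## Problem sizes and defaults used in the shipped benchmarks

The acceptance script and tests run the classification benchmark on a
proteome of 60 TFs (12 per superclass, 3 families each) and 120 non-TFs
without decoys (the separability benchmark measures the features, not the
deliberately confusable decoys). The similarity-recovery benchmark uses a
20-family panel (4 families per superclass, 5 members each, divergence
0.2); the threshold-curve benchmark uses a 25-family graded panel (5
families per superclass at divergences 0.02–0.3, 5 members each) so the
data contain both trivial close-homolog transfers — which dominate at high
thresholds — and non-trivial ones. These sizes give stable statistics
while keeping the exact Smax evaluations cheap; all randomness flows from
a single seed argument.

## Known limitations

* Exhaustive (non-heuristic) alignment: quadratic in database size.
* Single-pass PSSM profiles; no iterative profile refinement.
* The hit-threshold rule (per-window significance α_hit) is one reasonable
  convention; balanced type-I/type-II conventions exist and would shift
  absolute Smax values, though not the normalized similarity's fixed
  points.
* The local alignment kernel is computed in direct (non-log) space; for
  sequences much longer than typical DBDs it can overflow and the
  normalized value degrades to 0.
* Merged consensus profiles keep overhangs, so repeated merging of
  dissimilar motifs lengthens profiles; their similarity computations then
  use the coarsened (approximate) score distributions.
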