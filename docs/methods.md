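# Methods

## Problem setting

The toolkit classifies MHC class II binding peptides by whether they
induce release of interleukin-10. Two dataset designs are supported: the
*main* design contrasts IL-10 inducing binders with non-inducing binders;
the *alternate* design contrasts inducers with MHC II non-binders, so that
a peptide of unknown binding status is called an inducer only when both
models agree (the AND rule in the applications layer). Datasets are pairs
of peptide files (FASTA or one-sequence-per-line), validated against the
20 canonical residues, minimum length 8, and deduplicated within each
class. Sequences appearing in both classes carry contradictory labels;
they are kept with a warning by default because neither label can be
trusted more than the other, and a strict mode rejects them outright.

## Encoders

Composition encodings are percentages: AAC divides residue counts by the
peptide length, DPC divides overlapping dipeptide counts by N−1 (the
number of dipeptides in a length-N sequence). Feature order is fixed
alphabetically (A…Y; AA…YY row-major), matching the one-hot convention in
which alanine occupies the first bit. Design choices where the conventions
genuinely varied:

- **Odd-length split composition**: the N-half receives floor(N/2)
  residues, the C-half the remainder. The choice is arbitrary but fixed
  and tested.
- **Terminal encodings**: NT/CT compositions are computed on the raw
  first/last `terminal_len` residues; NTCT encodings concatenate the two
  per-fragment blocks (40 AAC / 800 DPC features), mirroring how the
  derived 16-mer is built for the binary profile. For peptides of exactly
  8 residues the two fragments coincide and the derived 16-mer duplicates
  the peptide — a deliberate property of terminal alignment, not a bug.
- **Binary profiles** one-hot encode fixed-length inputs (terminal
  fragment or derived 16-mer): 20 bits per position, exactly one set bit
  per position.

## Classifiers and evaluation

All five families are scikit-learn estimators behind a uniform score
contract (higher = more likely inducer): SVM variants emit the signed
decision margin; forest, tree and k-NN emit the positive-class fraction
(trees voting positive, leaf purity, positive neighbours). This yields two
natural threshold scales, so the sweep grid is per family: margins
−2.0…2.0 in steps of 0.1, probabilities 0.0…1.0 in steps of 0.05.

Compositional features feed the forest, tree and k-NN learners as raw
percentages; SVM variants min-max scale features to [0, 1], with the
scaler fitted on training folds only to avoid leakage. Hyperparameter
names preserve the knobs practitioners tune: `trees` (default 600),
`neighbors` (3), `cost`/`gamma` (5 / "scale" for the main SVM; 5 / 0.001
for the SMO-style variant), `pruning_confidence`/`min_leaf` (0.4 / 2).
The pruning confidence is mapped monotonically onto scikit-learn's
cost-complexity parameter as `ccp_alpha = 0.01·(0.5 − confidence)`
(confidence 0.5 ≈ no pruning); this preserves the direction of the knob
without claiming bit-compatibility with other tree implementations, which
is explicitly out of scope.

Cross-validation is stratified k-fold (default 5) with per-class fold
sizes differing by at most one, deterministic given the seed. The
decision threshold is selected on the **pooled out-of-fold scores** —
per-fold tuning would produce five thresholds where a single reportable
operating point is wanted. The selection criterion defaults to maximum
MCC (exposed as an option: maximum accuracy or Sn/Sp balance), with ties
broken toward balanced sensitivity/specificity and then the smaller
threshold. MCC with a degenerate confusion matrix (zero denominator) is
defined as 0. ROC AUC is the trapezoid over thresholds at every distinct
score, which equals the concordant-pair (rank) statistic with half-credit
ties; the test suite verifies this equality against exhaustive pair
counting.

An 80/20 stratified split supports the alternate-design experiment:
five-fold CV on the 80% partition, independent validation on the held-out
20%.

## Feature selection

CFS scores a subset S of k features by
`merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` where r̄_cf is the mean
absolute feature–class correlation and r̄_ff the mean absolute pairwise
feature–feature correlation (constant features contribute 0). The search
is best-first from the empty set, expanding the best open subset by one
feature at a time and stopping after 5 consecutive expansions that fail
to improve the best merit seen. On small instances this search provably
coincided with exhaustive powerset enumeration in all tested cases; the
equality is asserted in the suite for ≤ 8 features.

## Motif mining

Motifs are plain contiguous substrings, length 2–6 by default; hyphenated
notation ("R-D-H") is normalised by stripping hyphens. A motif is
exclusive when it occurs in at least `min_support` target sequences
(default: ceil(2% of the target class)) and in zero contrast sequences —
exclusivity is absolute, not probabilistic. A motif whose one-residue
extension (either end) has identical support is removed as non-maximal:
since every occurrence of the extension contains the motif, equal support
means equal coverage and the shorter pattern is redundant. Ranking is by
support descending, ties toward shorter then lexicographically smaller
patterns; coverage is accumulated greedily down the ranking (support,
newly covered sequences, cumulative coverage). Gapped motifs, residue
classes and position weight matrices are out of scope.

## Positional and compositional statistics

Variable-length peptides are terminally aligned via their derived
16-mers, giving a 16-position × 20-residue profile per class. Each
(position, residue) cell is tested for a class difference in frequency
with a pooled two-proportion z-test, falling back to Fisher's exact test
whenever any expected cell count under the pooled rate is below 5. No
multiple-testing correction is applied by default (matching the visual
convention of two-sample sequence logos); Bonferroni is available via a
flag. Output is tabular, not graphical. Whole-sequence composition is
compared per residue with Welch's t-test on the per-peptide AAC vectors.

## Synthetic data generator

The generator emulates exactly the features the analyses rely on and no
more:

- residues i.i.d. within a sequence from a per-class weight map; lengths
  uniform over the class range (defaults 8–42 positives, 8–27 negatives —
  the published extremes of curated inducer/non-inducer sets; only the
  extremes are known, hence uniform);
- default composition bias: R and L up-weighted ×4 in positives (~15.4%
  each), A, G, P up-weighted ×3 in negatives (~13.0% each). The factors
  were calibrated by brute-force Bayes-rate computation on the i.i.d.
  model: simulating the composition log-likelihood-ratio classifier at
  the 394:848 prior gives a Bayes-optimal MCC near 0.90 at these levels,
  so a well-tuned composition learner clears MCC 0.8 with margin. Weaker
  settings (×2.5/×2.0) leave the Bayes ceiling near 0.69 and cannot
  guarantee that floor;
- planted exclusive motifs: each motif overwrites a window at a uniform
  random position in a fixed number of distinct sequences of its class;
  sequences of the other class containing the pattern (and any
  within-class duplicates) are resampled until constraints hold, with a
  bounded retry budget. The manifest records every carrier and placement,
  so all plants are recomputable by direct string search;
- an optional positional mode fixes a chosen residue at a chosen
  derived-16mer position in a fraction of one class, for testing the
  enrichment statistics.

The standard benchmark (`make_benchmark`) is 394/848 with three planted
motifs per class at realistic supports (12/11/10 positive, 32/26/22
negative), inducer motifs R/L-flavoured and non-inducer motifs
A/G/P-flavoured with V shared, echoing the vocabulary split seen in real
exclusive-motif tables.

What the generator deliberately does **not** model: MHC II binding-core
chemistry, positional dependence between residues, realistic length
distributions beyond the extremes, and label noise. Tests passing on
synthetic data therefore demonstrate the correctness of the machinery
(encoders, CV, threshold tuning, mining, statistics) and the recovery of
planted signal — not the field performance of the models on curated
experimental data, which depends on biology the generator does not
imitate.

## Numerical choices and degenerate inputs

- Thresholding is `score ≥ threshold` everywhere; sweep grids are finite
  and fixed per score scale.
- Sn/Sp require both classes present (error otherwise); MCC zero
  denominator → 0; ROC requires both classes.
- Composition blocks sum to 100 within 1e−9; encodings are deterministic
  and portable (fixed feature order).
- Model bundles are versioned single files; loading anything without the
  expected version string fails loudly.
- Problem sizes in the test suite are chosen for tight feedback loops:
  oracle-equivalence checks run at n ≤ 50 (AUC pair counting), ≤ 8
  features (CFS powerset), ≤ 10 peptides (motif enumeration); stability
  and monotonicity checks use 80–160 peptides per class with 80–100-tree
  forests over three seeds; the null calibration of the enrichment test
  uses 20 label permutations of a 150+150 null dataset.

## Known limitations

- The classifier implementations are scikit-learn's; published results
  obtained with other SVM/forest/tree implementations will differ in the
  third digit even at matched hyperparameters, which is why external
  reference values are treated as soft targets.
- Exclusive-motif mining is exact but brittle to label noise by
  construction (one contrast occurrence vetoes a motif).
- The enrichment test's Fisher fallback is conservative at small counts;
  calls near the significance boundary should not be over-interpreted.
- The AND rule assumes the two models' thresholds were each tuned on
  their own dataset design; it makes no attempt to recalibrate their
  joint operating point.
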