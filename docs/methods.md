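# Methods

This note documents the models, numerical conventions and design choices
behind `ecfuse`, in the spirit of a methods appendix: what is computed, the
defaults and why, what the synthetic data do and do not emulate, and the
known limitations.

## Structural branch: torsion-angle density

A protein backbone's conformation is summarized by the per-residue torsion
angle pairs (φ, ψ) — rotations about the N–Cα and Cα–C bonds — whose joint
distribution is the Ramachandran plot. These are rotation- and
translation-invariant, unlike raw coordinates, which makes them a natural
structural descriptor.

**PDB reading.** Only `ATOM` records for N, Cα and C are used; HETATM
records, waters and hydrogens are ignored. Multi-model files contribute only
their first model (one conformation per enzyme, one feature vector per
entry). Alternate locations resolve to the highest-occupancy conformer, ties
to the first listed. Non-standard residues with a complete backbone are kept:
torsions depend only on backbone geometry.

**Torsion computation.** For residue i inside a contiguous segment,
φᵢ = dihedral(C₍ᵢ₋₁₎, Nᵢ, Cαᵢ, Cᵢ) and ψᵢ = dihedral(Nᵢ, Cαᵢ, Cᵢ, N₍ᵢ₊₁₎);
only residues with both angles defined contribute, so a segment of n
residues yields n − 2 pairs, pooled over all chains. A C(i)–N(i+1) distance
above 2.5 Å (versus the 1.33 Å peptide bond) is treated as a chain break,
terminating the segment; this prevents spurious torsions across unmodeled
gaps. Angles follow the IUPAC sign convention and live in the half-open
range [−180°, 180°), with +180 mapped to −180 so binning is unambiguous.
The dihedral is computed by the atan2 cross/dot formulation, which is stable
near 0° and ±180°. Degenerate geometry (zero-length bonds, collinear
triples) raises rather than returning an arbitrary value.

**Density features.** The pairs are counted on a 19 × 19 grid. With an odd
bin count and the central bin centered at 0°, the bin width is 360/19 ≈
18.95° and the outer edges land exactly on ±180°, so every angle falls in
exactly one bin. The count grid is smoothed by convolution with a uniform
3 × 3 kernel — the smallest nontrivial moving average; the size is
configurable — under *periodic* boundary conditions, because torsion angles
are periodic quantities and zero-padding would bias the edge bins. Dividing
by the total count yields a probability mass function, making enzymes of
different lengths comparable. The grid is linearized row-major with φ as the
slow axis; any fixed order is equivalent for classification, but the order
is part of the on-disk feature format and therefore documented.

## Sequence branch: local-alignment similarity

Similarity S(i, j) between two sequences is the optimal Smith–Waterman
local-alignment score — the maximum cell of the affine-gap (Gotoh) dynamic
programming matrix — computed with Biopython's C-backed `PairwiseAligner`.
Local alignment (rather than global) accommodates insertions, deletions and
partial matches of arbitrary extent.

* Scoring defaults: BLOSUM62, gap open 11, gap extend 1 — the ubiquitous
  protein local-alignment setting; all configurable.
* Gap convention: a gap of length L costs open + L·extend, so a length-1
  gap costs 12 with the defaults. (`PairwiseAligner`'s `open_gap_score` is
  therefore set to −(open + extend).)
* Scores are memoized on unordered id pairs, so symmetric layouts (training
  vs training) cost one alignment per pair.

Two representations are derived from a query's similarities to the labeled
reference set, always excluding the query itself from every class set
("k ≠ j"; this keeps S(j, j) from inflating its own class during training):

* **X_AA (60-dim).** Per class, the scores are divided by the query's
  maximum similarity over *all* references — making the 10 equal bins on
  [0, 1] scale- and length-invariant — histogrammed (final bin closed at 1),
  and each block normalized to sum 1 so classes of different sizes are
  comparable. The value range and the per-block normalization are
  conventions chosen here; both are configurable.
* **f_AA (6-dim).** The per-class maximum similarity normalized over the six
  class maxima. If no class has a positive maximum the caller may request a
  flagged uniform fallback (1/6 each) instead of an error; the pipeline uses
  the fallback so that a single pathological query cannot abort a run.

## Classifiers

* **SVM**: RBF kernel with Platt-scaled, pairwise-coupled probabilities
  (scikit-learn `SVC(probability=True)`). The regularization C is selected
  from {1, 10, 100} by stratified cross-validation on the training portion;
  γ uses scikit-learn's `scale` heuristic.
* **Nearest neighbor**: hard prediction is the classic k-NN vote (k = 1
  default). Probabilities are inverse-distance-weighted votes among the k
  neighbors; since that is degenerate at k = 1, the k = 1 surrogate is a
  softmax over the negative per-class nearest distances (temperature 1 in
  feature-space units), with an exact hit receiving the full mass. This
  construction is not uniquely determined by the nearest-neighbor rule; it
  was chosen as the simplest distance-monotone probability that preserves
  the 1-NN decision.
* **Multi-label second stage**: binary relevance — six independent binary
  classifiers (shared method) on the fused 6-dimensional probability input.
  Binary relevance is the simplest architecture consistent with a 6-bit
  output. A class with no positive training example yields a constant-zero
  relevance model (with a warning). An all-zero prediction falls back to a
  one-hot vector at the top fused class, since every enzyme carries at
  least one function.
* **Multi-label probability base**: when the training set itself is
  multi-label, "the" class of a sample is ill-defined, so f_SI comes from a
  per-class ensemble instead of a forced single-label fit: six
  Platt-calibrated binary SVMs (or per-class nearest-carrier distances for
  NN), with the six positive-class outputs normalized to sum 1. This
  reduces to the single-label construction when every sample carries one
  class.
* Ties in any arg-max decision break to the lowest class index, for
  determinism.

## Fusion

Feature-level fusion concatenates [X_SI | X_AA] (421 dimensions) before a
single classifier. Decision-level fusion forms (1 − α)·f_SI + α·f_AA and
optimizes the scalar α on a grid of step 0.01 (the weight is conventionally
reported to two decimals). The objective is training-fold accuracy of the
fused arg-max for single-label runs, and fold-averaged cross-validated
subset accuracy of the trained second stage for multi-label runs. α is
selected strictly inside the training portion; the held-out split never
influences it.

**Tie-breaking.** On clean, well-separated data the objective is exactly
constant over wide α plateaus (and a degraded modality contributes
near-constant probability vectors, which widens them further), so the
arg-max alone does not identify a meaningful weight. Ties on the objective
therefore resolve by the mean decision margin of the fused probabilities
(smallest true-class probability minus largest false-class probability,
averaged over samples), and any remaining tie by the largest α. The margin
refinement makes the selected α track the more reliable modality even when
raw accuracy saturates, which is what the degradation analysis below
measures. A consequence worth knowing: on data where both branches are
perfect, α lands at the endpoint whose probabilities are most confident
(for the synthetic defaults, the structural SVM), not necessarily at the
sequence end.

## Evaluation

Single-label: the 6 × 6 confusion matrix C(x, y); overall accuracy
(trace/total) and balanced accuracy (mean per-class recall). Classes with
no true member in the evaluated set are excluded from the balanced mean
rather than contributing an undefined ratio.

Multi-label, over N enzymes with true/predicted label sets:

* Hamming-loss = (1/N) Σᵢ |predᵢ Δ trueᵢ| / 6, and 1 − Hamming-loss;
* Accuracy = mean Jaccard index |pred ∩ true| / |pred ∪ true|;
* sample-averaged precision, recall and F1;
* subset accuracy = fraction of exact set matches;
* macro precision/recall/F1 (per class, then averaged over all six);
* micro precision/recall/F1 (from class-summed TP/FP/FN);
* per-class 1-Hamming-loss (per-column binary accuracy).

Zero-denominator conventions: an empty prediction set contributes 0 to the
sample-averaged precision; a per-class ratio with a zero denominator
contributes 0 to its macro mean. These cases cannot arise from this
package's predictors (predictions are never empty) but the conventions keep
the metrics total and deterministic on arbitrary inputs. The per-sample
identity |Δ| = |∪| − |∩| gives subset accuracy ≤ Jaccard accuracy ≤
1 − Hamming-loss on every dataset, which the tests assert.

## Experiment protocol

The labeled data are split 80/20 — stratified by class for single-label
data, by label cardinality for multi-label data, so small classes stay
represented — into training/validation and an untouched test portion.
On the training portion only: the SVM's C is selected by stratified K-fold
accuracy, f_SI for α-optimization comes from out-of-fold predictions (never
resubstitution), f_AA uses leave-self-out, and α maximizes the configured
objective. Selection is sequential (classifier hyperparameters first, then
α), the simpler of the reasonable protocols. The final base model is refit
on the full training portion; at test time the reference set for the
sequence branch is the full training portion. The multi-label second stage
is trained on the *out-of-fold* fused probabilities, so it sees inputs with
test-like calibration. Reports are deterministic given (config, seed).

In `mixed` mode single-label enzymes (as one-hot label vectors) and
multi-label enzymes pool into one training set and the multi-label path
runs on the pooled data.

## Synthetic data

The generator emulates the *shape* of the real problem — PDB structures,
FASTA sequences, a six-class label table with optional multi-label rows —
with controllable, seeded class signal:

* **Structure**: each class owns a dominant Ramachandran basin (weight
  0.85, versus 0.03 for each other basin) among six 2D Gaussians with 10°
  standard deviation: α-helix (−60, −45), β-sheet (−120, 130), left-handed
  helix (60, 45), polyproline-II (−70, 150), extended (−150, −60) and the
  bridge region (−90, 10). One dominant basin per class keeps the *pooled*
  mixture of a multi-label enzyme (the average of its classes' mixtures)
  distinguishable from every single class and every other pair, which a
  blended-basin design does not. Sampled torsions are realized as 3D
  coordinates by sequential internal-to-Cartesian (NeRF) construction with
  ideal peptide geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω =
  180°), so written PDB files round-trip through the torsion extraction to
  within coordinate precision.
* **Sequence**: lengths uniform on 80–160; background residues uniform over
  the 20 amino acids; one distinctive 10-mer motif per carried class,
  built from low-background-frequency residues (W, C, H, M, Y, F, P) so
  BLOSUM62 local alignment separates classes cleanly, inserted at a random
  non-overlapping position.
* **Labels**: per-class counts are configurable; a multi-label fraction
  turns single labels into sets, with the number of extra labels drawn from
  a configurable distribution (the desk-scale defaults mirror a corpus that
  is mostly 2-label with rare 3- and 4-label enzymes).
* **Degradations**: `randomize_torsions` replaces class mixtures with
  uniform angles (structure carries no class signal);
  `scramble_motifs` inserts a *randomly chosen* class's motif
  (sequence composition stays motif-like, but the motif-class association
  — the actual signal — is destroyed). Note that merely permuting a
  motif's letters would preserve its composition and hence most of its
  local-alignment signal; scrambling the association is the degradation
  that actually decouples the modality from the labels.

What the generator does **not** emulate: real torsion densities (which
overlap heavily across EC classes — structure alone reaches only ~83% on
real data, far below what these well-separated basins allow), homology
structure within classes, sequence–structure consistency beyond the shared
label, side chains, or realistic residue composition. Passing tests
therefore demonstrate the correctness of the machinery and the qualitative
behavior of fusion, not real-data accuracy levels.

## Problem sizes

The shipped experiments use 6 × 50 enzymes (single- and multi-label) for
the recovery analyses and 6 × 30 for the degradation analyses, with
sequences of 80–160 residues and backbones of 60–120 residues — sizes at
which each full pipeline run (feature extraction, ~30k cached alignments,
cross-validated selection, final fit and evaluation) completes in well
under a minute on one CPU while leaving every class with double-digit
test membership.

## Known limitations

* The α reported on clean synthetic data reflects the margin tie-break, not
  a genuine accuracy difference between modalities; on data where the
  branches disagree the objective itself decides.
* Binary relevance ignores label correlations; classifier chains or label
  powerset methods are out of scope.
* The sequence branch requires a reference training set at prediction time
  (f_AA and X_AA are reference-relative by construction); structure-only
  prediction with a fusion model is an explicit error, not a silent
  fallback.
* mmCIF input, side-chain χ angles and structure validation/repair are out
  of scope; PDB coordinates carry three decimals, which perturbs recomputed
  torsions by up to ~0.2° on chains of the sizes used here.
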