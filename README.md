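# ecfuse

Enzyme function prediction from protein structure and sequence, fused.

Enzymes catalyze chemical reactions and are organized by the Enzyme
Commission (EC) code, whose first digit assigns one of six top-level
reaction classes: oxidoreductases (1), transferases (2), hydrolases (3),
lyases (4), isomerases (5) and ligases (6). Some enzymes are
multi-functional and carry several of these classes at once. `ecfuse`
predicts the class set of an enzyme from two complementary views of a PDB
structure and its amino-acid sequence, and is aimed at structural
bioinformaticians who want a transparent, fully reproducible baseline for
EC-class prediction with both single-label and multi-label evaluation.

## The model

**Structural branch (X_SI).** The backbone torsion angles φ (rotation about
N–Cα) and ψ (rotation about Cα–C) of every residue, pooled over all chains,
are histogrammed on a 19 × 19 grid over [−180°, 180°)² with the central bin
centered at 0° — a discretized Ramachandran density. The histogram is
smoothed with a uniform (moving-average) kernel under periodic boundary
conditions and normalized, giving a 361-dimensional probability vector per
enzyme.

**Sequence branch (X_AA, f_AA).** Pairwise similarity S(i, j) is the optimal
Smith–Waterman local-alignment score (BLOSUM62, affine gaps, open 11 /
extend 1). Against a labeled training set, the similarities of a query j
are summarized two ways:

* *X_AA* — for each class x, the scores to that class's training members
  are rescaled by the query's maximum training similarity and histogrammed
  into 10 bins on [0, 1]; the six blocks concatenate to 60 dimensions.
* *f_AA* — class probabilities from the per-class maxima:

      (f_AA)_x = max_{k ∈ class x, k ≠ j} S(k, j) / Σ_l max_{k ∈ class l, k ≠ j} S(k, j)

A query that is itself a training sample is excluded from every class set
(leave-self-out).

**Classifiers and fusion.** An SVM (RBF kernel, Platt-calibrated) or a
nearest-neighbor rule on X_SI produces structural class probabilities f_SI.
The two views combine either at the *feature level* (concatenation to 421
dimensions before classification) or at the *decision level*:

      f_fused = (1 − α) · f_SI + α · f_AA,  α ∈ [0, 1]

with α chosen by grid search (step 0.01) maximizing training-fold accuracy
(single-label) or cross-validated subset accuracy (multi-label). Single-label
prediction takes the arg-max class; multi-label prediction feeds the fused
probabilities to six binary-relevance classifiers that output a 6-bit class
membership vector (never all-zero: an empty prediction falls back to the top
fused class).

**Evaluation.** Single-label: confusion matrix, overall and balanced
accuracy. Multi-label: Hamming-loss (and its complement), Jaccard accuracy,
sample-averaged precision/recall/F1, subset accuracy, macro- and
micro-averaged precision/recall/F1, and per-class 1-Hamming-loss.

Because real PDB-scale training data are not bundled, the package ships a
first-class synthetic generator: each class owns a dominant Ramachandran
basin (mixtures of 2D Gaussians over (φ, ψ), built into ideal-geometry
backbones and written as standard PDB), and carries a distinctive sequence
motif inserted into background sequence. Class structure, multi-label
composition and per-modality degradation are all controllable and seeded.

## Worked example

```python
import ecfuse as ef

spec = ef.SyntheticSpec(n_per_class=(20,) * 6, seed=0)
dataset = ef.generate_dataset(spec)

config = ef.ExperimentConfig(mode="single_label", scheme="decision", seed=0)
bundle = ef.bundle_from_dataset(dataset, config)
report, artifact = ef.run_experiment(bundle, config)

print(f"held-out overall accuracy : {report['overall_accuracy']:.3f}")
print(f"held-out balanced accuracy: {report['balanced_accuracy']:.3f}")
print(f"optimized fusion weight   : alpha = {report['alpha']:.2f}")
```

Output:

```
held-out overall accuracy : 1.000
held-out balanced accuracy: 1.000
optimized fusion weight   : alpha = 0.00
```

The 120 synthetic enzymes are split 80/20 with stratification; α and the
SVM regularization are selected by 5-fold cross-validation on the training
portion only, and the report shows the held-out metrics. On this clean
synthetic set both branches separate the classes perfectly, so the
cross-validated objective ties across α and the tie resolves by decision
margin (here toward the structural side, whose calibrated probabilities are
the most confident). Degrading one modality moves α to the other endpoint —
see `docs/methods.md`.

The same workflow is available from the shell:

```bash
ecfuse generate --out data --n-per-class 20 --seed 0
ecfuse train --pdb-dir data/pdb --fasta data/sequences.fasta \
             --labels data/labels.csv --scheme decision \
             --mode single_label --seed 0 \
             --model-out model.pkl --report-out report.json
ecfuse predict --model model.pkl --pdb-dir data/pdb \
               --fasta data/sequences.fasta --out predictions.csv
```

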