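"""End-to-end experiment orchestration: split, cross-validate, fuse, evaluate.

The protocol mirrors the classification study the package implements: the
labeled data are split 80/20 (stratified) into a training/validation portion
and an independent test portion; classifier hyperparameters and the fusion
weight alpha are selected by 5-fold cross-validation on the training portion
only; the final model is refit on the full training portion and reported on
the untouched 20%.

Information-fusion schemes
--------------------------
* ``si_only``   -- base classifier on the structural density X_SI.
* ``aa_only``   -- the similarity-derived probabilities f_AA.
* ``feature``   -- one classifier on the concatenated [X_SI | X_AA] vector.
* ``decision``  -- convex combination (1 - alpha) f_SI + alpha f_AA with
  alpha optimized on the training folds.

Leakage rules: during training-fold feature construction each sample's own
similarity is excluded from its reference set (leave-self-out, "k != j");
at test time the reference set is the full training portion. Structural
probabilities f_SI used for alpha optimization and for training the
multi-label second stage are out-of-fold cross-validation predictions, never
resubstitution outputs.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classification import (
    MultiLabelModel,
    TrainedModel,
    predict_proba,
    train_multi_label,
    train_probability_base_multilabel,
    train_single_label,
)
from .evaluation import confusion_and_accuracies, multilabel_metrics
from .fusion import (
    FusionConfig,
    feature_level_fuse,
    fuse_probability_matrix,
    optimize_alpha,
)
from .sequence_similarity import (
    DEFAULT_SCORING,
    N_CLASSES,
    ScoringScheme,
    SequenceRecord,
    SimilarityMatrix,
    TrainingIndex,
    class_probabilities_aa,
    pairwise_similarities,
    read_fasta,
    similarity_features,
)
from .structural_features import (
    DEFAULT_KERNEL_SIZE,
    DEFAULT_N_BINS,
    structural_features,
)
from .structure_io import ProteinStructure, compute_backbone_torsions, parse_pdb

__all__ = [
    "ExperimentConfig",
    "DataBundle",
    "ModelArtifact",
    "load_inputs",
    "bundle_from_dataset",
    "run_experiment",
    "train_artifact",
    "evaluate_artifact",
    "predict",
    "save_artifact",
    "load_artifact",
]

Mode = Literal["single_label", "multi_label", "mixed"]
Scheme = Literal["si_only", "aa_only", "feature", "decision"]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; a (config, seed) pair fixes the report."""

    mode: Mode = "single_label"
    scheme: Scheme = "decision"
    base_method: str = "svm"  # classifier on X_SI (or fused features)
    second_stage_method: str = "svm"  # multi-label relevance classifier
    split_fraction: float = 0.8
    n_folds: int = 5
    seed: int = 0
    svm_c_grid: Sequence[float] = (1.0, 10.0, 100.0)
    nn_k: int = 1
    alpha_grid_step: float = 0.01
    n_bins: int = DEFAULT_N_BINS
    kernel_size: int = DEFAULT_KERNEL_SIZE
    scoring: ScoringScheme = field(default_factory=lambda: DEFAULT_SCORING)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class DataBundle:
    """Aligned per-enzyme inputs: X_SI rows, sequences and 6-bit labels."""

    ids: list[str]
    X_si: np.ndarray  # (n, n_bins**2)
    sequences: dict[str, SequenceRecord]
    labels: pd.DataFrame  # index ids, columns EC1..EC6

    def __post_init__(self) -> None:
        missing_seq = [i for i in self.ids if i not in self.sequences]
        if missing_seq:
            raise ValueError(f"ids missing a sequence: {missing_seq}")
        if list(self.labels.index) != self.ids:
            self.labels = self.labels.loc[self.ids]

    @property
    def label_matrix(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def primary_class(self) -> np.ndarray:
        """Lowest carried class per enzyme (the single label when unique)."""
        return self.label_matrix.argmax(axis=1) + 1

    def subset(self, ids: Sequence[str]) -> "DataBundle":
        pos = {e: k for k, e in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return DataBundle(
            list(ids),
            self.X_si[idx],
            {i: self.sequences[i] for i in ids},
            self.labels.loc[list(ids)],
        )


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a label CSV: either id + EC1..EC6 binary columns, or id + a
    comma-separated list of EC top digits in a 'classes' column."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    ec_cols = [f"EC{x}" for x in range(1, 7)]
    if all(c in df.columns for c in ec_cols):
        out = df[ec_cols].astype(int)
    elif "classes" in df.columns:
        rows = np.zeros((len(df), N_CLASSES), dtype=int)
        for i, val in enumerate(df["classes"]):
            for tok in str(val).split(","):
                rows[i, int(tok) - 1] = 1
        out = pd.DataFrame(rows, index=df.index, columns=ec_cols)
    else:
        raise ValueError(f"unrecognized label table format in {path}")
    if (out.to_numpy().sum(axis=1) == 0).any():
        raise ValueError("a label row has no positive class")
    return out


def load_inputs(
    pdb_dir: str | Path,
    fasta: str | Path,
    labels: str | Path,
    config: ExperimentConfig | None = None,
) -> DataBundle:
    """Load and align structures, sequences and labels from disk.

    Every labeled id must have both a PDB file named <id>.pdb under
    ``pdb_dir`` and a FASTA record; offenders are listed in the error.
    """
    config = config or ExperimentConfig()
    label_df = read_label_table(labels)
    sequences = {r.id: r for r in read_fasta(fasta)}
    pdb_dir = Path(pdb_dir)
    ids = list(label_df.index)
    missing = [
        i for i in ids if i not in sequences or not (pdb_dir / f"{i}.pdb").exists()
    ]
    if missing:
        raise ValueError(f"ids missing a structure or sequence: {missing}")
    X_si = np.vstack(
        [
            structural_features(
                compute_backbone_torsions(parse_pdb(pdb_dir / f"{i}.pdb", i)),
                n_bins=config.n_bins,
                kernel_size=config.kernel_size,
            ).values
            for i in ids
        ]
    )
    return DataBundle(ids, X_si, sequences, label_df)


def bundle_from_dataset(dataset, config: ExperimentConfig | None = None) -> DataBundle:
    """Build a DataBundle from an in-memory synthetic dataset."""
    config = config or ExperimentConfig()
    X_si = np.vstack(
        [
            structural_features(
                compute_backbone_torsions(s),
                n_bins=config.n_bins,
                kernel_size=config.kernel_size,
            ).values
            for s in dataset.structures
        ]
    )
    ids = [s.id for s in dataset.structures]
    return DataBundle(
        ids, X_si, {r.id: r for r in dataset.sequences}, dataset.labels
    )


def split_ids(bundle: DataBundle, config: ExperimentConfig) -> tuple[list[str], list[str]]:
    """Stratified train/test id split.

    Single-label data stratify by class; multi-label data stratify by label
    cardinality. Falls back to plain shuffling when a stratum is too small.
    """
    labels = bundle.label_matrix
    if config.mode == "single_label":
        strata = bundle.primary_class
    else:
        strata = labels.sum(axis=1)
    try:
        train, test = train_test_split(
            bundle.ids,
            train_size=config.split_fraction,
            random_state=config.seed,
            stratify=strata,
            shuffle=True,
        )
    except ValueError:  # a stratum with a single member
        train, test = train_test_split(
            bundle.ids,
            train_size=config.split_fraction,
            random_state=config.seed,
            shuffle=True,
        )
    return list(train), list(test)


def _stratified_folds(y: np.ndarray, config: ExperimentConfig) -> StratifiedKFold:
    """K folds stratified by class, capped so every fold sees every class."""
    counts = np.bincount(y)
    smallest = int(counts[counts > 0].min())
    n_splits = max(2, min(config.n_folds, smallest))
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)


def _select_svm_c(
    X: np.ndarray, y: np.ndarray, config: ExperimentConfig
) -> float:
    """Pick the SVM regularization C by stratified K-fold accuracy."""
    if config.base_method != "svm" or len(config.svm_c_grid) == 1:
        return float(config.svm_c_grid[0])
    skf = _stratified_folds(y, config)
    best_c, best_score = float(config.svm_c_grid[0]), -1.0
    for c in config.svm_c_grid:
        scores = []
        for tr, va in skf.split(X, y):
            model = train_single_label(
                X[tr], y[tr], "svm", svm_c=c, random_state=config.seed
            )
            probs = np.vstack([p.values for p in predict_proba(model, X[va])])
            scores.append(np.mean(probs.argmax(axis=1) + 1 == y[va]))
        score = float(np.mean(scores))
        if score > best_score:
            best_c, best_score = float(c), score
    return best_c


def _fit_base(
    X: np.ndarray,
    y: np.ndarray,
    Y: np.ndarray,
    config: ExperimentConfig,
    svm_c: float,
    multi: bool,
) -> TrainedModel:
    """The structural probability base: single-label classifier, or the
    per-class ensemble when the training set is multi-label."""
    if multi:
        return train_probability_base_multilabel(
            X, Y, config.base_method, svm_c=svm_c, random_state=config.seed
        )
    return train_single_label(
        X, y, config.base_method,
        svm_c=svm_c, nn_k=config.nn_k, random_state=config.seed,
    )


def _cv_probabilities(
    X: np.ndarray,
    y: np.ndarray,
    Y: np.ndarray,
    config: ExperimentConfig,
    svm_c: float,
    multi: bool,
) -> np.ndarray:
    """Out-of-fold class probabilities of the base classifier on X."""
    skf = _stratified_folds(y, config)
    P = np.zeros((len(X), N_CLASSES))
    for tr, va in skf.split(X, y):
        model = _fit_base(X[tr], y[tr], Y[tr], config, svm_c, multi)
        P[va] = np.vstack([p.values for p in predict_proba(model, X[va])])
    return P


@dataclass
class ModelArtifact:
    """Everything needed to predict new enzymes; built from training data only."""

    config: ExperimentConfig
    train_ids: list[str]
    training_index: TrainingIndex
    reference_sequences: dict[str, SequenceRecord]
    base_model: TrainedModel | None  # on X_SI (or fused features)
    second_stage: MultiLabelModel | None  # multi-label relevance models
    alpha: float | None
    svm_c: float
    cv_alpha_objective: dict[str, float] = field(default_factory=dict)

    @property
    def version(self) -> int:
        return 1


def _train_probability_sources(
    train: DataBundle,
    config: ExperimentConfig,
    svm_c: float,
    need_si: bool = True,
    need_aa: bool = True,
) -> tuple[np.ndarray | None, np.ndarray | None, SimilarityMatrix | None, TrainingIndex]:
    """Out-of-fold f_SI and leave-self-out f_AA for the training portion."""
    index = TrainingIndex.from_labels(
        {
            i: [c + 1 for c in np.flatnonzero(row)]
            for i, row in zip(train.ids, train.label_matrix)
        }
    )
    S = P_aa = P_si = None
    if need_aa:
        seqs = [train.sequences[i] for i in train.ids]
        S = pairwise_similarities(seqs, seqs, config.scoring)
        P_aa = np.vstack(
            [
                class_probabilities_aa(i, S, index, on_zero="uniform").values
                for i in train.ids
            ]
        )
    if need_si:
        multi = config.mode in ("multi_label", "mixed")
        P_si = _cv_probabilities(
            train.X_si, train.primary_class, train.label_matrix, config, svm_c, multi
        )
    return P_si, P_aa, S, index


def _sequence_feature_matrix(
    ids: Sequence[str], S: SimilarityMatrix, index: TrainingIndex
) -> np.ndarray:
    return np.vstack([similarity_features(i, S, index).values for i in ids])


def train_artifact(train: DataBundle, config: ExperimentConfig) -> ModelArtifact:
    """Fit the configured scheme on the training portion only."""
    y_train = train.primary_class
    Y_train = train.label_matrix
    multi = config.mode in ("multi_label", "mixed")

    svm_c = _select_svm_c(train.X_si, y_train, config)
    alpha: float | None = None
    base_model: TrainedModel | None = None
    second_stage: MultiLabelModel | None = None
    cv_obj: dict[str, float] = {}

    if config.scheme in ("si_only", "decision"):
        need_aa = config.scheme == "decision"
        P_si, P_aa, S, index = _train_probability_sources(
            train, config, svm_c, need_aa=need_aa
        )
        base_model = _fit_base(train.X_si, y_train, Y_train, config, svm_c, multi)
        if config.scheme == "decision":
            fusion_cfg = FusionConfig(
                grid_step=config.alpha_grid_step,
                objective="subset_accuracy" if multi else "accuracy",
                second_stage_method=config.second_stage_method,
                cv_folds=config.n_folds,
            )
            alpha, scores = optimize_alpha(
                P_si, P_aa, Y_train if multi else y_train,
                fusion_cfg, random_state=config.seed, return_objective=True,
            )
            grid = fusion_cfg.grid
            cv_obj = {
                "alpha_star": float(alpha),
                "objective_at_alpha_star": float(scores[np.searchsorted(grid, alpha)]),
                "objective_si_only": float(scores[0]),
                "objective_aa_only": float(scores[-1]),
            }
            P_train = fuse_probability_matrix(P_si, P_aa, alpha)
        else:
            P_train = P_si
        if multi:
            second_stage = train_multi_label(
                P_train, Y_train, config.second_stage_method,
                random_state=config.seed,
            )
    elif config.scheme == "aa_only":
        _, P_aa, S, index = _train_probability_sources(
            train, config, svm_c, need_si=False
        )
        if multi:
            second_stage = train_multi_label(
                P_aa, Y_train, config.second_stage_method, random_state=config.seed
            )
    elif config.scheme == "feature":
        _, _, S, index = _train_probability_sources(
            train, config, svm_c, need_si=False
        )
        X_aa = _sequence_feature_matrix(train.ids, S, index)
        X_fused = np.vstack(
            [feature_level_fuse(si, aa) for si, aa in zip(train.X_si, X_aa)]
        )
        base_model = train_single_label(
            X_fused, y_train, config.base_method,
            svm_c=svm_c, nn_k=config.nn_k, random_state=config.seed,
        )
        if multi:
            second_stage = train_multi_label(
                X_fused, Y_train, config.second_stage_method,
                random_state=config.seed,
            )
    else:
        raise ValueError(f"unknown scheme {config.scheme!r}")

    return ModelArtifact(
        config=config,
        train_ids=list(train.ids),
        training_index=index,
        reference_sequences={i: train.sequences[i] for i in train.ids},
        base_model=base_model,
        second_stage=second_stage,
        alpha=alpha,
        svm_c=svm_c,
        cv_alpha_objective=cv_obj,
    )


def _test_probabilities(
    artifact: ModelArtifact, bundle: DataBundle
) -> tuple[np.ndarray | None, np.ndarray | None, SimilarityMatrix]:
    """f_SI and f_AA of new enzymes against the artifact's reference set."""
    config = artifact.config
    S = P_aa = None
    if config.scheme != "si_only":
        refs = [artifact.reference_sequences[i] for i in artifact.train_ids]
        queries = [bundle.sequences[i] for i in bundle.ids]
        S = pairwise_similarities(queries, refs, config.scoring)
        P_aa = np.vstack(
            [
                class_probabilities_aa(
                    i, S, artifact.training_index, on_zero="uniform"
                ).values
                for i in bundle.ids
            ]
        )
    P_si = None
    if artifact.base_model is not None and config.scheme in ("si_only", "decision"):
        P_si = np.vstack(
            [p.values for p in predict_proba(artifact.base_model, bundle.X_si)]
        )
    return P_si, P_aa, S


def _fused_scores(
    artifact: ModelArtifact, bundle: DataBundle
) -> tuple[np.ndarray, np.ndarray]:
    """(probability matrix used for decisions, relevance-model input matrix)."""
    config = artifact.config
    if config.scheme == "feature":
        _, _, S = _test_probabilities(artifact, bundle)
        X_aa = _sequence_feature_matrix(bundle.ids, S, artifact.training_index)
        X_fused = np.vstack(
            [feature_level_fuse(si, aa) for si, aa in zip(bundle.X_si, X_aa)]
        )
        P = np.vstack([p.values for p in predict_proba(artifact.base_model, X_fused)])
        return P, X_fused
    P_si, P_aa, _ = _test_probabilities(artifact, bundle)
    if config.scheme == "si_only":
        return P_si, P_si
    if config.scheme == "aa_only":
        return P_aa, P_aa
    fused = fuse_probability_matrix(P_si, P_aa, artifact.alpha)
    return fused, fused


def evaluate_artifact(artifact: ModelArtifact, test: DataBundle) -> dict:
    """Full metric report of the artifact on a held-out bundle."""
    probs, relevance_input = _fused_scores(artifact, test)
    report: dict = {
        "n_test": len(test.ids),
        "scheme": artifact.config.scheme,
        "mode": artifact.config.mode,
        "alpha": artifact.alpha,
        "svm_c": artifact.svm_c,
    }
    if artifact.config.mode == "single_label":
        y_pred = probs.argmax(axis=1) + 1
        cm, overall, balanced = confusion_and_accuracies(test.primary_class, y_pred)
        report.update(
            overall_accuracy=overall,
            balanced_accuracy=balanced,
            confusion_matrix=cm.counts.tolist(),
        )
    else:
        Y_pred = artifact.second_stage.predict(relevance_input, fallback_probs=probs)
        result = multilabel_metrics(test.label_matrix, Y_pred)
        report.update(result.as_dict())
        report["per_class_one_minus_hamming"] = (
            result.per_class_one_minus_hamming.tolist()
        )
    return report


def run_experiment(bundle: DataBundle, config: ExperimentConfig) -> tuple[dict, ModelArtifact]:
    """Split, train (with CV-based selection) and report on the held-out 20%."""
    train_ids, test_ids = split_ids(bundle, config)
    train = bundle.subset(train_ids)
    test = bundle.subset(test_ids)
    artifact = train_artifact(train, config)
    report = evaluate_artifact(artifact, test)
    report.update(
        n_train=len(train_ids),
        seed=config.seed,
        cv_alpha_objective=artifact.cv_alpha_objective,
    )
    return report, artifact


def predict(
    artifact: ModelArtifact,
    structures: Sequence[ProteinStructure],
    sequences: Sequence[SequenceRecord],
) -> pd.DataFrame:
    """Predict new enzymes against the artifact's training reference set.

    Returns a DataFrame with the six fused class probabilities, the ranked
    classes (most probable first), the hard top class, and — when the
    artifact carries a multi-label second stage — the 6-bit label vector.

    Raises
    ------
    ValueError
        If structures and sequences do not pair up id-for-id (sequence
        features are reference-dependent; structure-only input is an error
        for any scheme that uses sequence information).
    """
    struct_ids = [s.id for s in structures]
    seq_ids = [s.id for s in sequences]
    if struct_ids != seq_ids:
        raise ValueError(
            "structures and sequences must pair up id-for-id; "
            f"got {struct_ids} vs {seq_ids}"
        )
    config = artifact.config
    X_si = np.vstack(
        [
            structural_features(
                compute_backbone_torsions(s),
                n_bins=config.n_bins,
                kernel_size=config.kernel_size,
            ).values
            for s in structures
        ]
    )
    labels = pd.DataFrame(
        np.ones((len(struct_ids), N_CLASSES), dtype=int),  # placeholder, unused
        index=struct_ids,
        columns=[f"EC{x}" for x in range(1, 7)],
    )
    bundle = DataBundle(struct_ids, X_si, {r.id: r for r in sequences}, labels)
    probs, relevance_input = _fused_scores(artifact, bundle)
    out = pd.DataFrame(
        probs, index=struct_ids, columns=[f"p_EC{x}" for x in range(1, 7)]
    )
    ranked = np.argsort(-probs, axis=1, kind="stable") + 1
    out["ranked_classes"] = [",".join(map(str, row)) for row in ranked]
    out["top_class"] = probs.argmax(axis=1) + 1
    if artifact.second_stage is not None:
        Y = artifact.second_stage.predict(relevance_input, fallback_probs=probs)
        for x in range(1, 7):
            out[f"EC{x}"] = Y[:, x - 1]
    out.index.name = "id"
    return out


def save_artifact(artifact: ModelArtifact, path: str | Path) -> None:
    """Serialize a trained artifact (pickle, versioned)."""
    with open(path, "wb") as fh:
        pickle.dump({"format_version": artifact.version, "artifact": artifact}, fh)


def load_artifact(path: str | Path) -> ModelArtifact:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["artifact"]


def report_to_json(report: dict, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
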