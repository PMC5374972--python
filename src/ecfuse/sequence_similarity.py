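"""Smith-Waterman similarities and sequence-derived features (X_AA, f_AA).

Sequence similarity between two proteins is quantified as the optimal local
alignment score S(i, j): the maximum cell of the Smith-Waterman dynamic
programming matrix with affine gaps. From the similarities of a query j to a
reference (training) set partitioned into the six EC top-level classes, two
representations are derived:

* ``similarity_features`` -- per class, the scores are rescaled by the
  query's maximum training similarity and summarized as a 10-bin histogram
  on [0, 1]; the six blocks are concatenated into the 60-dimensional X_AA.
* ``class_probabilities_aa`` -- per class, the maximum similarity, normalized
  over the six per-class maxima, giving the 6-dimensional probability f_AA.

A query that is itself a training sample is always excluded from every class
set (leave-self-out), so S(j, j) never inflates its own class.

Gap penalties follow the convention that a gap of length L costs
open + L * extend; the defaults (BLOSUM62, open 11, extend 1) are the common
protein local-alignment settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRecord",
    "ScoringScheme",
    "SimilarityMatrix",
    "TrainingIndex",
    "SequenceFeatureVector",
    "ClassProbabilityVector",
    "sw_score",
    "pairwise_similarities",
    "similarity_features",
    "class_probabilities_aa",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS + "X")

N_CLASSES = 6
DEFAULT_N_BINS = 10


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence over the 20-letter alphabet plus X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} has characters outside the alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scoring and affine gap penalties for local alignment.

    Either a named substitution matrix (e.g. "BLOSUM62") or explicit
    match/mismatch scores. A gap of length L is penalized open + L * extend.
    """

    matrix: str | None = "BLOSUM62"
    match: float | None = None
    mismatch: float | None = None
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.matrix is None and (self.match is None or self.mismatch is None):
            raise ValueError("provide either a matrix name or match/mismatch scores")

    @property
    def signature(self) -> tuple:
        return (self.matrix, self.match, self.mismatch, self.gap_open, self.gap_extend)


DEFAULT_SCORING = ScoringScheme()


@lru_cache(maxsize=8)
def _aligner(signature: tuple):
    from Bio import Align
    from Bio.Align import substitution_matrices

    matrix, match, mismatch, gap_open, gap_extend = signature
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # PairwiseAligner scores a length-L gap as open_gap + (L-1) * extend_gap
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_score(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> float:
    """Optimal Smith-Waterman local alignment score of two sequences.

    Returns the maximum cell of the affine-gap (Gotoh) dynamic-programming
    matrix; non-negative, and symmetric for a symmetric substitution matrix.

    Raises
    ------
    ValueError
        On empty sequences or residues missing from the substitution matrix.
    """
    seq_a = a.sequence if isinstance(a, SequenceRecord) else a
    seq_b = b.sequence if isinstance(b, SequenceRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(scoring.signature)
    if aligner.substitution_matrix is not None:
        known = set(str(c) for c in aligner.substitution_matrix.alphabet)
        bad = (set(seq_a) | set(seq_b)) - known
        if bad:
            raise ValueError(f"residues not covered by the substitution matrix: {sorted(bad)}")
    return float(aligner.score(seq_a, seq_b))


@dataclass
class SimilarityMatrix:
    """Local-alignment scores S(reference k, query j), rows=references."""

    scores: pd.DataFrame  # index: reference ids, columns: query ids

    @property
    def reference_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def query_ids(self) -> list[str]:
        return list(self.scores.columns)

    def score(self, reference_id: str, query_id: str) -> float:
        return float(self.scores.at[reference_id, query_id])

    def column(self, query_id: str) -> pd.Series:
        return self.scores[query_id]

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def pairwise_similarities(
    queries: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> SimilarityMatrix:
    """Compute S(k, j) for every reference k and query j.

    Scores are memoized on unordered id pairs, so the symmetric overlap of
    queries and references (the typical leave-self-out layout, where every
    training sample is both) is computed once per pair.
    """
    cache: dict[frozenset, float] = {}
    mat = np.zeros((len(references), len(queries)))
    for jq, q in enumerate(queries):
        for kr, r in enumerate(references):
            key = frozenset((q.id, r.id))
            if key not in cache:
                cache[key] = sw_score(r, q, scoring)
            mat[kr, jq] = cache[key]
    return SimilarityMatrix(
        pd.DataFrame(mat, index=[r.id for r in references], columns=[q.id for q in queries])
    )


@dataclass
class TrainingIndex:
    """For each EC class 1..6, the ids of training samples carrying it.

    A multi-label training sample appears in every class set it carries.
    """

    class_members: dict[int, set[str]] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, labels: Mapping[str, Sequence[int]]) -> "TrainingIndex":
        """Build from a mapping id -> iterable of EC classes (1..6)."""
        members: dict[int, set[str]] = {x: set() for x in range(1, N_CLASSES + 1)}
        for sample_id, classes in labels.items():
            if not classes:
                raise ValueError(f"sample {sample_id!r} has no class")
            for x in classes:
                if x not in members:
                    raise ValueError(f"class {x} out of range 1..{N_CLASSES}")
                members[x].add(sample_id)
        return cls(members)

    def members(self, ec_class: int, exclude: str | None = None) -> set[str]:
        ids = self.class_members.get(ec_class, set())
        return ids - {exclude} if exclude is not None else set(ids)

    @property
    def all_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.class_members.values():
            out |= ids
        return out


@dataclass
class SequenceFeatureVector:
    """X_AA: six concatenated 10-bin similarity histograms (length 60)."""

    values: np.ndarray
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != N_CLASSES * self.n_bins:
            raise ValueError(
                f"expected {N_CLASSES * self.n_bins} values, got {self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    def block(self, ec_class: int) -> np.ndarray:
        """The 10-bin histogram block of one class (1-based)."""
        start = (ec_class - 1) * self.n_bins
        return self.values[start : start + self.n_bins]


@dataclass
class ClassProbabilityVector:
    """Six non-negative class probabilities summing to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} values, got {self.values.size}")
        if np.any(self.values < -1e-12):
            raise ValueError("negative class probability")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.values.sum()}, not 1")

    def __len__(self) -> int:
        return self.values.size

    def argmax_class(self) -> int:
        """Most probable class, 1-based; ties resolve to the lowest index."""
        return int(np.argmax(self.values)) + 1


def similarity_features(
    query_id: str,
    similarities: SimilarityMatrix,
    index: TrainingIndex,
    n_bins: int = DEFAULT_N_BINS,
) -> SequenceFeatureVector:
    """The 60-dimensional X_AA feature vector of one query.

    For each class x the similarities of the query to the class's training
    samples (query excluded) are rescaled by the query's maximum similarity
    over *all* training samples, histogrammed into ``n_bins`` equal bins on
    [0, 1] (final bin closed at 1) and the block normalized to sum 1.

    Raises
    ------
    ValueError
        If a class set is empty after self-exclusion, or all similarities
        of the query to the training set are zero.
    """
    col = similarities.column(query_id)
    train_ids = index.all_ids - {query_id}
    if not train_ids:
        raise ValueError("empty training set after self-exclusion")
    global_max = max(col[k] for k in train_ids)
    if global_max <= 0:
        raise ValueError(f"all-zero similarities for query {query_id!r}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    blocks = []
    for x in range(1, N_CLASSES + 1):
        members = index.members(x, exclude=query_id)
        if not members:
            raise ValueError(f"class {x} has no training sample (after self-exclusion)")
        rescaled = np.array([col[k] / global_max for k in sorted(members)])
        counts, _ = np.histogram(rescaled, bins=edges)  # final bin closed at 1
        blocks.append(counts / counts.sum())
    return SequenceFeatureVector(np.concatenate(blocks), n_bins=n_bins)


def class_probabilities_aa(
    query_id: str,
    similarities: SimilarityMatrix,
    index: TrainingIndex,
    on_zero: str = "error",
) -> ClassProbabilityVector:
    """f_AA: per-class maximum similarity normalized over all classes.

    Component x is max_{k in class x, k != query} S(k, query) divided by the
    sum of the six per-class maxima.

    Parameters
    ----------
    on_zero : "error" or "uniform"
        What to do when no class has a positive maximum: raise, or fall back
        to the uninformative uniform vector (1/6, ..., 1/6).
    """
    col = similarities.column(query_id)
    maxima = np.zeros(N_CLASSES)
    for x in range(1, N_CLASSES + 1):
        members = index.members(x, exclude=query_id)
        if not members:
            raise ValueError(f"class {x} has no training sample (after self-exclusion)")
        maxima[x - 1] = max(col[k] for k in members)
    total = maxima.sum()
    if total <= 0:
        if on_zero == "uniform":
            return ClassProbabilityVector(np.full(N_CLASSES, 1.0 / N_CLASSES))
        raise ValueError(f"no positive similarity to any class for {query_id!r}")
    return ClassProbabilityVector(maxima / total)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read amino-acid sequences from a FASTA file."""
    from Bio import SeqIO

    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
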