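"""Feature-level and decision-level fusion of structure and sequence.

Feature-level fusion concatenates the 361-dimensional structural density
X_SI with the 60-dimensional sequence-similarity histogram X_AA into one
421-dimensional vector before classification.

Decision-level fusion combines the two class-probability vectors by a
convex combination, fused = (1 - alpha) * f_SI + alpha * f_AA, with a single
scalar weight alpha in [0, 1] chosen on training data by exhaustive grid
search: alpha = 0 keeps only structure, alpha = 1 only sequence. Ties on the
objective resolve to the largest alpha (preferring sequence information).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .classification import train_multi_label
from .evaluation import multilabel_metrics
from .sequence_similarity import ClassProbabilityVector, N_CLASSES

__all__ = [
    "FusionConfig",
    "feature_level_fuse",
    "fuse_probabilities",
    "fuse_probability_matrix",
    "optimize_alpha",
]

Objective = Literal["accuracy", "subset_accuracy"]


@dataclass
class FusionConfig:
    """Settings for decision-level fusion and the alpha grid search."""

    alpha: float | None = None  # fixed weight; None means optimize
    grid_step: float = 0.01
    objective: Objective = "accuracy"
    # second stage settings, used only for the subset-accuracy objective
    second_stage_method: str = "svm"
    cv_folds: int = 5
    tie_break: Literal["largest", "smallest"] = "largest"

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        n = round(1.0 / self.grid_step)
        if n < 1 or abs(n * self.grid_step - 1.0) > 1e-9:
            raise ValueError("grid_step must divide 1 evenly")

    @property
    def grid(self) -> np.ndarray:
        n = round(1.0 / self.grid_step)
        return np.linspace(0.0, 1.0, n + 1)


def feature_level_fuse(x_si: np.ndarray, x_aa: np.ndarray) -> np.ndarray:
    """Concatenate X_SI (361) and X_AA (60) into a 421-dim feature vector."""
    x_si = np.asarray(getattr(x_si, "values", x_si), dtype=float).ravel()
    x_aa = np.asarray(getattr(x_aa, "values", x_aa), dtype=float).ravel()
    if x_si.size != 361 or x_aa.size != 60:
        raise ValueError(
            f"expected lengths 361 and 60, got {x_si.size} and {x_aa.size}"
        )
    return np.concatenate([x_si, x_aa])


def fuse_probabilities(
    f_si: ClassProbabilityVector,
    f_aa: ClassProbabilityVector,
    alpha: float,
) -> ClassProbabilityVector:
    """Component-wise (1 - alpha) * f_SI + alpha * f_AA."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return ClassProbabilityVector((1.0 - alpha) * f_si.values + alpha * f_aa.values)


def fuse_probability_matrix(
    P_si: np.ndarray, P_aa: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized fusion of aligned (n, 6) probability matrices."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return (1.0 - alpha) * np.asarray(P_si, float) + alpha * np.asarray(P_aa, float)


def _as_matrix(probs: Sequence) -> np.ndarray:
    rows = [np.asarray(getattr(p, "values", p), dtype=float).ravel() for p in probs]
    P = np.vstack(rows)
    if P.shape[1] != N_CLASSES:
        raise ValueError(f"probability rows must have {N_CLASSES} entries")
    return P


def _single_label_objective(P: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(P.argmax(axis=1) + 1 == y))


def _mean_margin(P: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-sample margin: smallest true-class probability minus largest
    false-class probability (single labels are one-element true sets)."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        Y = np.zeros((len(P), N_CLASSES), dtype=bool)
        Y[np.arange(len(P)), labels - 1] = True
    else:
        Y = labels.astype(bool)
    true_min = np.where(Y, P, np.inf).min(axis=1)
    false_max = np.where(~Y, P, -np.inf).max(axis=1)
    false_max = np.where(np.isneginf(false_max), 0.0, false_max)
    return float(np.mean(true_min - false_max))


def _subset_accuracy_cv(
    P: np.ndarray, Y: np.ndarray, config: FusionConfig, random_state: int
) -> float:
    """Fold-averaged subset accuracy of the second stage trained on fused P."""
    from sklearn.model_selection import KFold

    n = len(P)
    folds = min(config.cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=random_state)
    scores = []
    for train_idx, val_idx in kf.split(P):
        if Y[train_idx].sum(axis=0).max() == 0:
            continue
        model = train_multi_label(
            P[train_idx], Y[train_idx], method=config.second_stage_method,
            random_state=random_state,
        )
        pred = model.predict(P[val_idx])
        scores.append(multilabel_metrics(Y[val_idx], pred).subset_accuracy)
    if not scores:
        raise ValueError("no valid cross-validation fold for alpha optimization")
    return float(np.mean(scores))


def optimize_alpha(
    train_probs_si: Sequence,
    train_probs_aa: Sequence,
    train_labels: np.ndarray,
    config: FusionConfig | None = None,
    *,
    random_state: int = 0,
    return_objective: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Exhaustive grid search for the fusion weight alpha.

    For the single-label objective ("accuracy") ``train_labels`` is a class
    array in 1..6 and each candidate alpha is scored by the accuracy of the
    fused argmax. For the multi-label objective ("subset_accuracy")
    ``train_labels`` is an (n, 6) binary matrix and each alpha is scored by
    the cross-validated subset accuracy of the binary-relevance second stage
    trained on the fused probabilities.

    Ties resolve to the largest alpha by default.
    """
    if config is None:
        config = FusionConfig()
    if len(train_probs_si) == 0 or len(train_probs_aa) == 0:
        raise ValueError("probability lists and labels must be aligned and non-empty")
    P_si = _as_matrix(train_probs_si)
    P_aa = _as_matrix(train_probs_aa)
    labels = np.asarray(train_labels)
    if len(P_si) != len(P_aa) or len(P_si) != len(labels) or len(P_si) == 0:
        raise ValueError("probability lists and labels must be aligned and non-empty")
    grid = config.grid
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    scores = np.empty(grid.size)
    margins = np.empty(grid.size)
    for gi, alpha in enumerate(grid):
        fused = fuse_probability_matrix(P_si, P_aa, alpha)
        if config.objective == "accuracy":
            scores[gi] = _single_label_objective(fused, labels)
        elif config.objective == "subset_accuracy":
            scores[gi] = _subset_accuracy_cv(fused, labels, config, random_state)
        else:
            raise ValueError(f"unknown objective {config.objective!r}")
        margins[gi] = _mean_margin(fused, labels)
    # Objective ties (wide plateaus are common when one source is clean or
    # one is uninformative) resolve by the mean decision margin of the fused
    # probabilities, so alpha tracks the informative modality; any remaining
    # tie resolves to the largest alpha (preferring sequence information).
    best = scores.max()
    candidates = np.flatnonzero(np.isclose(scores, best, rtol=0, atol=1e-12))
    best_margin = margins[candidates].max()
    candidates = candidates[
        np.isclose(margins[candidates], best_margin, rtol=0, atol=1e-12)
    ]
    idx = candidates[-1] if config.tie_break == "largest" else candidates[0]
    alpha_star = float(grid[idx])
    if return_objective:
        return alpha_star, scores
    return alpha_star
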