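"""Smoothed 2D torsion-angle density features (X_SI).

The (phi, psi) pairs of a protein are histogrammed on a 19 x 19 grid over
[-180, 180)^2 whose central bin is centered at 0 degrees, smoothed by a
moving average (convolution with a uniform kernel) and normalized to a
probability mass function, then linearized row-major (phi-major) to the
361-dimensional structural feature vector.

With an odd number of bins n and the central bin centered at 0, the bin
width is 360/n and the outermost bin edges land exactly on +/-180, so every
angle in [-180, 180) falls in exactly one bin. Torsion angles are periodic,
so smoothing uses periodic (wrap-around) boundary conditions on the torus,
which preserves total mass and avoids biasing the edge bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .structure_io import TorsionAngleSet

__all__ = [
    "StructuralFeatureVector",
    "torsion_histogram",
    "smooth_and_normalize",
    "structural_features",
    "bin_index",
    "DEFAULT_N_BINS",
    "DEFAULT_KERNEL_SIZE",
]

DEFAULT_N_BINS = 19
DEFAULT_KERNEL_SIZE = 3


@dataclass
class StructuralFeatureVector:
    """Linearized smoothed torsion density; entries >= 0 and sum to 1."""

    values: np.ndarray  # length n_bins**2
    n_bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.n_bins**2:
            raise ValueError(
                f"expected {self.n_bins**2} values, got {self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def grid(self) -> np.ndarray:
        """The density as an (n_bins, n_bins) grid, phi along axis 0."""
        return self.values.reshape(self.n_bins, self.n_bins)

    @property
    def bin_edges(self) -> np.ndarray:
        """Shared bin edges in degrees: -180, -180 + w, ..., +180."""
        return np.linspace(-180.0, 180.0, self.n_bins + 1)


def bin_index(angle: float | np.ndarray, n_bins: int) -> np.ndarray:
    """Map angles in [-180, 180) to bin indices 0..n_bins-1.

    Bins have width w = 360/n_bins and the central bin (index
    (n_bins - 1)/2) spans [-w/2, +w/2), i.e. it is centered at 0 degrees.
    For odd n_bins the first bin starts exactly at -180.
    """
    width = 360.0 / n_bins
    idx = (n_bins - 1) // 2 + np.floor(
        (np.asarray(angle, dtype=float) + width / 2.0) / width
    ).astype(int)
    return np.clip(idx, 0, n_bins - 1)  # guard against roundoff at +/-180


def torsion_histogram(
    torsions: TorsionAngleSet, n_bins: int = DEFAULT_N_BINS
) -> np.ndarray:
    """2D sample histogram of (phi, psi) pairs on an n_bins x n_bins grid.

    Axis 0 is phi, axis 1 is psi. ``n_bins`` must be odd so that one bin is
    centered at 0 degrees. Every pair falls in exactly one bin and the grid
    total equals the number of pairs.
    """
    if n_bins % 2 == 0 or n_bins < 1:
        raise ValueError(f"n_bins must be odd and positive, got {n_bins}")
    if len(torsions) == 0:
        raise ValueError("empty torsion set")
    grid = np.zeros((n_bins, n_bins), dtype=int)
    i = bin_index(torsions.phi, n_bins)
    j = bin_index(torsions.psi, n_bins)
    np.add.at(grid, (i, j), 1)
    return grid


def smooth_and_normalize(
    grid: np.ndarray, kernel_size: int = DEFAULT_KERNEL_SIZE
) -> StructuralFeatureVector:
    """Moving-average smoothing on the torus, then normalization to sum 1.

    The count grid is convolved with a kernel_size x kernel_size uniform
    kernel under periodic boundary conditions and divided by the total
    count, so the result is a probability mass function over the bins.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"grid must be square 2D, got shape {grid.shape}")
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
    if np.any(grid < 0):
        raise ValueError("negative counts in histogram grid")
    total = grid.sum()
    if total <= 0:
        raise ValueError("all-zero histogram grid")
    smoothed = uniform_filter(grid, size=kernel_size, mode="wrap")
    density = smoothed / total
    return StructuralFeatureVector(density.ravel(), n_bins=grid.shape[0])


def structural_features(
    torsions: TorsionAngleSet,
    n_bins: int = DEFAULT_N_BINS,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
) -> StructuralFeatureVector:
    """Histogram + smoothing + normalization in one step (X_SI)."""
    return smooth_and_normalize(torsion_histogram(torsions, n_bins), kernel_size)
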