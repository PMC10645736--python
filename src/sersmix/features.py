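"""Characteristic-peak feature extraction and Kennard-Stone splitting.

The classifier operates not on the full 200-1700 cm^-1 spectrum (dominated
by irrelevant signal) but on windows around the characteristic bands of the
two analytes: five centres (559, 609, 668, 675, 990 cm^-1) with five grid
points on each side, i.e. 5 x 11 = 55 wavenumbers.  Training and test sets
are chosen deterministically by the Kennard-Stone maximin procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .simulate import LabeledSpectrumSet

__all__ = [
    "DEFAULT_PEAK_CENTERS",
    "FeatureMatrix",
    "SplitIndices",
    "select_peak_windows",
    "kennard_stone_split",
]

#: Characteristic-peak centres (cm^-1) used for the 55-wavenumber feature set.
DEFAULT_PEAK_CENTERS = (559.0, 609.0, 668.0, 675.0, 990.0)


@dataclass
class FeatureMatrix:
    """Samples x selected-wavenumber intensities with column provenance.

    ``column_meta`` holds one ``(peak_center, offset)`` pair per column,
    where ``offset`` is the signed grid-point offset from the snapped peak
    centre.  Overlapping windows keep duplicate columns so the column count
    is exactly ``n_peaks * (2 * half_points + 1)``.
    """

    values: np.ndarray
    column_meta: list[tuple[float, int]]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must match label count")
        if self.values.shape[1] != len(self.column_meta):
            raise ValueError("column count must match column_meta length")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        return [f"peak{int(c)}_offset{k:+d}" for c, k in self.column_meta]


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test indices covering all samples.

    ``train`` is in Kennard-Stone selection order; ``test`` is ascending.
    """

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "train", np.asarray(self.train, dtype=int))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=int))
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test indices must be disjoint")


def snap_to_grid(grid: np.ndarray, center: float) -> int:
    """Index of the grid point nearest ``center`` (ties -> lower wavenumber)."""
    return int(np.argmin(np.abs(grid - center)))


def select_peak_windows(spectra: LabeledSpectrumSet,
                        centers: tuple[float, ...] = DEFAULT_PEAK_CENTERS,
                        half_points: int = 5) -> FeatureMatrix:
    """Extract intensity windows of ``2*half_points + 1`` grid points around
    each peak centre, concatenated in the listed order."""
    grid = spectra.wavenumbers
    intensities = spectra.intensities
    cols: list[np.ndarray] = []
    meta: list[tuple[float, int]] = []
    for center in centers:
        i = snap_to_grid(grid, center)
        lo, hi = i - half_points, i + half_points
        if lo < 0 or hi >= grid.size:
            raise ValueError(
                f"window of peak {center} cm^-1 (grid points {lo}..{hi}) "
                f"extends past the grid edge"
            )
        cols.append(intensities[:, lo:hi + 1])
        meta.extend((center, k) for k in range(-half_points, half_points + 1))
    return FeatureMatrix(np.hstack(cols), meta, spectra.labels)


def kennard_stone_split(features: FeatureMatrix | np.ndarray,
                        n_train: int = 50) -> SplitIndices:
    """Classic Kennard-Stone maximin selection of a training set.

    Seeds with the pair at maximum Euclidean distance, then repeatedly adds
    the sample whose minimum distance to the already-selected set is
    largest.  Fully deterministic; ties are broken by the lowest index.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = X.shape[0]
    if not (2 <= n_train < n):
        raise ValueError(f"n_train must be in [2, {n - 1}], got {n_train}")
    D = squareform(pdist(X, metric="euclidean"))
    # seed pair: argmax over the flattened matrix picks the lexicographically
    # first (i, j) among ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_train:
        min_dist_masked = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(min_dist_masked))
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    test = np.flatnonzero(remaining)
    return SplitIndices(np.array(selected), test)
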