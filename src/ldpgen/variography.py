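"""Directional empirical variograms of binary 3D masks.

The empirical (semi)variogram at lag h is

    gamma(h) = 1 / (2 n(h)) * sum_i (z(x_i) - z(x_i + h))^2

where the sum runs over all n(h) voxel pairs separated by exactly h. Here
lags are pure shifts of k = 1..max_lag voxels along one grid axis, so pairs
are formed by aligning the array with a shifted copy of itself: no angular
tolerance, no wrap-around, no padding. Every voxel of the array takes part,
lesion and background alike. For a {0,1} field gamma is bounded by 0.5.

Lag distances in mm use the spacing of the lag axis, so anisotropic voxels
yield different distance grids per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask

__all__ = [
    "AXES",
    "LagSpec",
    "EmpiricalVariogram",
    "default_max_lag",
    "empirical_variogram",
    "variograms_xyz",
]

#: Axis labels in array-axis order; axis 0/1/2 of the array is MNB x/y/z.
AXES = ("x", "y", "z")

#: Variograms of binary lesion masks carry their correlation information in
#: roughly the first 15 mm of lag distance; the default lag count per run is
#: chosen so the largest lag stays within this span.
MAX_LAG_DISTANCE_MM = 15.0


@dataclass(frozen=True)
class LagSpec:
    """Number of one-voxel-wide distance classes (lags) per axis."""

    max_lag: int

    def __post_init__(self) -> None:
        if int(self.max_lag) != self.max_lag or self.max_lag < 1:
            raise ValueError(f"max_lag must be an integer >= 1, got {self.max_lag}")
        object.__setattr__(self, "max_lag", int(self.max_lag))

    def validate_for(self, shape: tuple[int, int, int]) -> None:
        short = [n for n in shape if self.max_lag >= n]
        if short:
            raise ValueError(
                f"max_lag={self.max_lag} must be smaller than every axis length; "
                f"volume shape is {shape}"
            )


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Per-direction sequence of (lag distance mm, gamma, pair count)."""

    direction: str
    lags_voxels: np.ndarray
    distances_mm: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in AXES:
            raise ValueError(f"direction must be one of {AXES}, got {self.direction!r}")
        for name in ("lags_voxels", "distances_mm", "gamma", "pair_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.lags_voxels) == len(self.distances_mm)
            == len(self.gamma) == len(self.pair_counts)
        ):
            raise ValueError("lag, distance, gamma and pair-count arrays must align")
        if np.any(np.diff(self.distances_mm) <= 0):
            raise ValueError("distances_mm must be strictly increasing")
        if np.any(self.gamma < 0):
            raise ValueError("gamma must be non-negative")

    @property
    def max_lag(self) -> int:
        return int(self.lags_voxels[-1])


def default_max_lag(spacing: tuple[float, float, float], shape: tuple[int, int, int]) -> int:
    """Lag count covering lag distances up to ~15 mm on the coarsest axis.

    floor(15 mm / coarsest spacing): e.g. 1.5 mm voxels give 10 lags, 1 mm
    voxels give 15. Clamped so every axis keeps at least one voxel pair.
    """
    coarsest = max(spacing)
    n = int(np.floor(MAX_LAG_DISTANCE_MM / coarsest))
    n = max(n, 1)
    return min(n, min(shape) - 1)


def empirical_variogram(
    mask: BinaryMask, direction: str, lag_spec: LagSpec
) -> EmpiricalVariogram:
    """Directional empirical variogram of a binary mask along one grid axis.

    For each lag k = 1..max_lag, gamma(k) is half the mean squared difference
    over all axis-aligned voxel pairs separated by exactly k voxels along
    ``direction``. Edge pairs that would leave the array are simply not
    formed, so the pair count at lag k along an axis of length n_d is
    (n_d - k) times the number of voxels in the perpendicular plane.
    """
    if direction not in AXES:
        raise ValueError(f"direction must be one of {AXES}, got {direction!r}")
    lag_spec.validate_for(mask.shape)

    axis = AXES.index(direction)
    data = mask.data
    n_axis = data.shape[axis]
    plane = data.size // n_axis

    max_lag = lag_spec.max_lag
    lags = np.arange(1, max_lag + 1)
    gamma = np.empty(max_lag, dtype=np.float64)
    counts = np.empty(max_lag, dtype=np.int64)

    head = [slice(None)] * 3
    tail = [slice(None)] * 3
    for k in lags:
        head[axis] = slice(0, n_axis - k)
        tail[axis] = slice(k, n_axis)
        # {0,1} data: squared difference is XOR, so count mismatching pairs.
        diff = data[tuple(head)] != data[tuple(tail)]
        n_pairs = (n_axis - k) * plane
        gamma[k - 1] = int(np.count_nonzero(diff)) / (2.0 * n_pairs)
        counts[k - 1] = n_pairs

    spacing = mask.spacing[axis]
    return EmpiricalVariogram(
        direction=direction,
        lags_voxels=lags,
        distances_mm=lags * spacing,
        gamma=gamma,
        pair_counts=counts,
    )


def variograms_xyz(
    mask: BinaryMask, lag_spec: LagSpec
) -> tuple[EmpiricalVariogram, EmpiricalVariogram, EmpiricalVariogram]:
    """Directional empirical variograms along the three major axes x, y, z."""
    return tuple(empirical_variogram(mask, d, lag_spec) for d in AXES)
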