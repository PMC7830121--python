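"""Synthetic binary lesion volumes and the brute-force variogram oracle.

These generators stand in for downloadable MS brain phantoms during testing:
every stage of the pipeline can be exercised on volumes with known
statistical or geometric structure. All generators are pure functions of
their arguments (including the seed); no other module draws random numbers.

The brute-force variogram here is a deliberately literal triple-loop
transcription of the semivariance definition, kept independent from the
shift-based production implementation so it can serve as its oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, save_mask
from .variography import AXES, EmpiricalVariogram

__all__ = [
    "LesionSceneSpec",
    "bernoulli_field",
    "ellipsoid_scene",
    "brute_force_variogram",
    "write_scene_nifti",
]


def bernoulli_field(
    shape: tuple[int, int, int],
    p: float,
    seed: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> BinaryMask:
    """I.i.d. binary field: each voxel is 1 with probability p.

    An analytic test field: for any lag h >= 1 the expected semivariance is
    p(1 - p), independent of direction.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    data = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(data=data, spacing=spacing,
                      source_name=f"bernoulli_p{p}_seed{seed}")


@dataclass(frozen=True)
class LesionSceneSpec:
    """Recipe for a synthetic lesion scene: a union of ellipsoids.

    Semi-axes are in mm, so anisotropic lesions (e.g. stretched along z,
    as periventricular MS lesions often are) can be emulated by setting
    rz > rx, ry. Centers are drawn uniformly inside the volume; ``jitter``
    scales an additional per-lesion random offset (in voxels). Lesions are
    clipped at the volume bounds (no wrap-around).
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 12
    radius_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radius_mm):
            raise ValueError(f"semi-axes must be positive, got {self.radius_mm}")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")


def ellipsoid_scene(spec: LesionSceneSpec) -> BinaryMask:
    """Render a lesion scene as a crisp binary mask (union of ellipsoids)."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    data = np.zeros(spec.shape, dtype=np.uint8)

    # physical coordinates of voxel centers, mm
    gx = np.arange(nx)[:, None, None] * dx
    gy = np.arange(ny)[None, :, None] * dy
    gz = np.arange(nz)[None, None, :] * dz

    centers = rng.random((spec.n_lesions, 3)) * np.array(
        [nx * dx, ny * dy, nz * dz]
    )
    if spec.jitter > 0:
        centers = centers + rng.normal(scale=spec.jitter, size=centers.shape) * np.array(
            [dx, dy, dz]
        )
    rx, ry, rz = spec.radius_mm
    for cx, cy, cz in centers:
        inside = (
            ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 + ((gz - cz) / rz) ** 2
        ) <= 1.0
        data |= inside.astype(np.uint8)

    return BinaryMask(
        data=data,
        spacing=spec.spacing,
        source_name=f"scene_seed{spec.seed}",
    )


def brute_force_variogram(mask: BinaryMask, direction: str, max_lag: int) -> EmpiricalVariogram:
    """Literal triple-loop semivariance: the test oracle.

    For every lag k, walk every voxel, form the pair (voxel, voxel + k along
    ``direction``) when the partner lies inside the array, and accumulate the
    squared value difference. Same contract as the production implementation,
    deliberately slow and direct.
    """
    if direction not in AXES:
        raise ValueError(f"direction must be one of {AXES}, got {direction!r}")
    axis = AXES.index(direction)
    data = np.asarray(mask.data, dtype=np.int64)
    nx, ny, nz = data.shape
    if max_lag >= data.shape[axis]:
        raise ValueError(f"max_lag={max_lag} too large for axis length {data.shape[axis]}")

    step = [0, 0, 0]
    step[axis] = 1
    gamma, counts = [], []
    for k in range(1, max_lag + 1):
        sq_sum = 0
        n_pairs = 0
        for i in range(nx):
            for j in range(ny):
                for m in range(nz):
                    i2, j2, m2 = i + k * step[0], j + k * step[1], m + k * step[2]
                    if i2 >= nx or j2 >= ny or m2 >= nz:
                        continue
                    d = data[i, j, m] - data[i2, j2, m2]
                    sq_sum += d * d
                    n_pairs += 1
        gamma.append(sq_sum / (2.0 * n_pairs))
        counts.append(n_pairs)

    lags = np.arange(1, max_lag + 1)
    return EmpiricalVariogram(
        direction=direction,
        lags_voxels=lags,
        distances_mm=lags * mask.spacing[axis],
        gamma=np.array(gamma),
        pair_counts=np.array(counts, dtype=np.int64),
    )


def write_scene_nifti(mask: BinaryMask, path: str | os.PathLike) -> str:
    """Write a synthetic scene to NIfTI-1 for end-to-end CLI tests."""
    return save_mask(mask, path)
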