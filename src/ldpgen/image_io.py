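"""Reading NIfTI-1 / Analyze-7.5 lesion volumes and binarizing probability maps.

Input volumes are expected in Montreal Normal Brain (MNB) template geometry.
Array axes 1/2/3 are taken as the MNB x/y/z directions exactly as stored in
the file; no reorientation from the header affine is attempted (a warning is
logged when the affine carries a non-trivial rotation, so users can spot
inputs that were not normalized as expected).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["VoxelVolume", "BinaryMask", "load_volume", "binarize", "save_mask"]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar voxel grid with per-axis spacing in mm.

    Attributes
    ----------
    data : np.ndarray
        3D array of voxel values (float).
    spacing : tuple of float
        (dx, dy, dz) voxel edge lengths in mm, strictly positive.
    source_name : str
        Basename of the originating file ("" for in-memory volumes).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {data.ndim}D shape {data.shape}")
        if any(n < 2 for n in data.shape):
            raise ValueError(
                f"each axis needs at least 2 voxels for variography, got shape {data.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive finite values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded {0, 1} lesion mask — the variography substrate.

    ``lesion_voxel_count`` is derived from the data; ``threshold_used`` records
    the binarization threshold, or ``"none"`` for masks built directly as binary.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_name: str = ""
    threshold_used: float | str = "none"
    lesion_voxel_count: int = field(init=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {data.ndim}D shape {data.shape}")
        if any(n < 2 for n in data.shape):
            raise ValueError(
                f"each axis needs at least 2 voxels for variography, got shape {data.shape}"
            )
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            bad = values[~np.isin(values, (0, 1))]
            raise ValueError(f"mask voxels must be exactly 0 or 1; found values {bad[:5]}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive finite values, got {self.spacing}")
        object.__setattr__(self, "data", data.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "lesion_voxel_count", int(data.sum()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def lesion_fraction(self) -> float:
        return self.lesion_voxel_count / self.data.size

    def as_volume(self) -> VoxelVolume:
        """View this mask as a plain scalar volume (e.g. for re-thresholding)."""
        return VoxelVolume(
            data=self.data.astype(np.float64),
            spacing=self.spacing,
            source_name=self.source_name,
        )


def load_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a NIfTI-1 (.nii/.nii.gz) or Analyze-7.5 (.hdr/.img) volume.

    An Analyze pair may be named by either member. Header scale slope /
    intercept are applied to the voxel values. A trailing singleton 4th
    dimension is squeezed with a warning; any other non-3D layout is rejected.

    Raises
    ------
    FileNotFoundError
        If ``path`` (or its Analyze partner) does not exist.
    ValueError
        If the image is not explicitly 3D or the header is unreadable.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"input image not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header-specific types
        raise ValueError(f"cannot read image header of {path}: {exc}") from exc

    data = np.asanyarray(img.get_fdata(dtype=np.float64))
    shape = data.shape
    nonsingleton = [n for n in shape if n > 1]
    if data.ndim > 3:
        extra = shape[3:]
        if all(n == 1 for n in extra):
            logger.warning(
                "%s: header declares %dD shape %s; squeezing trailing singleton "
                "dimension(s) to 3D", path, data.ndim, shape,
            )
            data = data.reshape(shape[:3])
        else:
            raise ValueError(
                f"{path}: volume is {data.ndim}D with shape {shape}, not 3D. "
                "Make sure input files are explicitly 3D."
            )
    elif data.ndim < 3 or len(nonsingleton) < 3:
        raise ValueError(
            f"{path}: volume has shape {shape}, not 3D. "
            "Make sure input files are explicitly 3D."
        )

    zooms = img.header.get_zooms()[:3]
    _warn_if_rotated(img, path)
    return VoxelVolume(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        source_name=os.path.basename(path),
    )


def _warn_if_rotated(img, path: str) -> None:
    affine = img.affine
    if affine is None:
        return
    rot = np.asarray(affine)[:3, :3]
    # Off-diagonal terms indicate a rotation/shear the loader deliberately ignores.
    off = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off) > 1e-6 * max(1.0, np.abs(rot).max())):
        logger.warning(
            "%s: header affine carries a non-identity rotation; axes are used "
            "as stored (no reorientation applied)", path,
        )


def binarize(vol: VoxelVolume, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map to a binary lesion mask.

    A voxel becomes lesion (1) iff its value is *strictly greater* than
    ``threshold``; all other voxels become background (0). Already-binary
    input thresholded at 0.5 is returned with identical content.

    Raises
    ------
    ValueError
        If ``threshold`` is outside [0, 1] or the volume contains NaNs.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    n_nan = int(np.isnan(vol.data).sum())
    if n_nan:
        raise ValueError(f"volume {vol.source_name or '<memory>'} contains {n_nan} NaN voxel(s)")
    data = (vol.data > threshold).astype(np.uint8)
    return BinaryMask(
        data=data,
        spacing=vol.spacing,
        source_name=vol.source_name,
        threshold_used=float(threshold),
    )


def save_mask(mask: BinaryMask, path: str | os.PathLike) -> str:
    """Write a mask (or any binary volume) as NIfTI-1 with its spacing."""
    path = os.fspath(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path
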