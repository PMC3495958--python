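"""Shared image/mask data model, NIfTI I/O and the morphological primitives
reused by every pipeline stage.

Conventions
-----------
* A :class:`Volume` is a 3D scalar array plus a voxel-to-world affine.  The
  acquisition slice axis is the **third** array axis; every "2D" operation
  (dilation, watershed, diffusion, region labelling) acts on axis-0 x axis-1
  planes independently, matching thick-slice axial FLAIR acquisitions.
* Masks are stored as boolean arrays and written to disk as uint8 {0, 1}.
* 3D connectivity is face connectivity (6 neighbours); 2D connectivity is the
  4-neighbour cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "SLICE_AXIS",
    "CROSS_2D",
    "Volume",
    "BinaryMask",
    "LabelMap",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "save_mask",
    "binarize_probability",
    "largest_component_3d",
    "dilate_2d",
    "tissue_interface",
    "label_slices_4conn",
]

#: index of the acquisition slice axis in all data arrays
SLICE_AXIS = 2

#: 2D 1-voxel structuring element, 4-connectivity
CROSS_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: same cross embedded in 3D so ndimage operations never propagate
#: between slices
CROSS_IN_PLANE_3D = CROSS_2D[:, :, None]

#: 6-connectivity (face neighbours) in 3D
FACE_CONN_3D = ndimage.generate_binary_structure(3, 1)


class GridMismatchError(ValueError):
    """Two images that must share a voxel grid do not."""


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world transform.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).  Stored as float64.
    affine:
        4x4 voxel-to-world matrix.  If omitted, a diagonal affine is built
        from ``spacing``.
    spacing:
        (dx, dy, dz) voxel size in mm.  Derived from ``affine`` when not
        given explicitly.
    """

    data: np.ndarray
    affine: np.ndarray = None
    spacing: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite intensities")
        if self.affine is None:
            sp = self.spacing if self.spacing is not None else (1.0, 1.0, 1.0)
            self.affine = np.diag([sp[0], sp[1], sp[2], 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.spacing is None:
            self.spacing = tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return self.shape == other.shape


@dataclass
class BinaryMask:
    """A boolean voxel mask on the grid of a reference :class:`Volume`."""

    data: np.ndarray
    grid: Volume = None

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3D")
        if self.grid is not None and self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        """Mask volume in mL (voxel count x voxel volume / 1000)."""
        vv = self.grid.voxel_volume_mm3 if self.grid is not None else 1.0
        return self.count() * vv / 1000.0


@dataclass
class LabelMap:
    """Non-negative integer region labelling; 0 is reserved for unlabeled."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer")
        if self.data.min() < 0:
            raise ValueError("LabelMap labels must be non-negative")


def _check_same_shape(a, b, what="inputs"):
    if a.data.shape != b.data.shape:
        raise GridMismatchError(f"{what} live on different grids: "
                                f"{a.data.shape} vs {b.data.shape}")


def load_volume(path) -> Volume:
    """Load a NIfTI-1 volume.

    Intensities are only rescaled by the NIfTI ``scl_slope``/``scl_inter``
    fields (applied by nibabel).  Non-3D images and non-finite voxels are
    hard errors naming the offending file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite intensities (NaN/Inf voxels)")
    return Volume(data=data, affine=np.asarray(img.affine))


def save_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path, affine=None) -> None:
    if affine is None:
        affine = mask.grid.affine if mask.grid is not None else np.eye(4)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def binarize_probability(prob: Volume, threshold: float = 0.5) -> BinaryMask:
    """Binarise a probability map, keeping voxels with probability strictly
    over ``threshold``."""
    lo, hi = prob.data.min(), prob.data.max()
    if lo < 0.0 or hi > 1.0:
        raise ValueError(
            f"probability map values outside [0, 1]: range [{lo:g}, {hi:g}]")
    return BinaryMask(data=prob.data > threshold, grid=prob)


def largest_component_3d(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Keep only the largest 6-connected component of a 3D mask.

    Ties are broken deterministically in favour of the component whose
    minimum linear voxel index is smallest (which is the first component
    encountered in raster-scan labelling).  An empty mask is returned
    unchanged with a warning.
    """
    if connectivity != 6:
        raise ValueError("only 6-connectivity is supported")
    labels, n = ndimage.label(mask.data, structure=FACE_CONN_3D)
    if n == 0:
        warnings.warn("largest_component_3d: mask is empty", stacklevel=2)
        return BinaryMask(data=np.zeros_like(mask.data, dtype=bool),
                          grid=mask.grid)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    # argmax returns the smallest label among ties; ndimage labels components
    # in raster-scan order of first encounter, so this is the component with
    # the smallest minimum linear index.
    keep = int(np.argmax(counts))
    return BinaryMask(data=labels == keep, grid=mask.grid)


def dilate_2d(mask: BinaryMask) -> BinaryMask:
    """Per-slice morphological dilation with the 2D 4-connected cross.

    No propagation between slices: the structuring element has unit extent
    along the slice axis.
    """
    out = ndimage.binary_dilation(mask.data, structure=CROSS_IN_PLANE_3D)
    return BinaryMask(data=out, grid=mask.grid)


def tissue_interface(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Interface between two tissues: intersection of the two per-slice
    dilated masks."""
    _check_same_shape(mask_a, mask_b, "interface masks")
    out = dilate_2d(mask_a).data & dilate_2d(mask_b).data
    return BinaryMask(data=out, grid=mask_a.grid)


def label_slices_4conn(mask: BinaryMask) -> LabelMap:
    """Label the 2D 4-connected components of each slice.

    Labels are unique across the whole volume (consecutive integers starting
    at 1); 0 marks background.
    """
    out = np.zeros(mask.data.shape, dtype=np.int32)
    offset = 0
    for k in range(mask.data.shape[SLICE_AXIS]):
        sl = mask.data[:, :, k]
        lab, n = ndimage.label(sl, structure=CROSS_2D)
        out[:, :, k] = np.where(lab > 0, lab + offset, 0)
        offset += n
    return LabelMap(data=out)
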