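"""Volume and mask handling: NIfTI-1 I/O, isotropic resampling, rim geometry.

Conventions used throughout the package:

* voxel values are Hounsfield units (HU) stored as ``float32``/``float64``;
* masks are ``uint8`` grids with values in ``{0, 1}``, aligned voxel-for-voxel
  with their parent volume;
* indices are 0-based, coordinates refer to voxel *centers*, and world
  coordinates come from the NIfTI affine (spacing on the diagonal, origin in
  the translation column);
* physical lengths (dilation margins, spacings) are millimetres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger("rimradiomics")

__all__ = [
    "CTVolume",
    "VOIMask",
    "LesionRegions",
    "read_volume",
    "write_volume",
    "read_mask",
    "resample_isotropic",
    "dilate_mask",
    "make_regions",
]


class ValidationError(ValueError):
    """Raised when an argument violates an operation's contract."""


class EmptyMaskError(ValidationError):
    """Raised when a mask with no foreground voxels is supplied."""


@dataclass
class CTVolume:
    """A 3D CT intensity grid with voxel spacing and world origin.

    Attributes
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Voxel intensities in HU.
    spacing : tuple of float
        Voxel edge length per axis, in mm.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValidationError(
                f"expected a 3D volume, got ndim={self.intensities.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VOIMask:
    """A binary volume-of-interest mask aligned with a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"expected a 3D mask, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be 0/1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))


@dataclass
class LesionRegions:
    """Tumor mask, its metric dilation, and the peritumoral rim.

    Satisfies ``tumor ⊆ dilated``, ``rim = dilated ∧ ¬tumor`` and
    ``rim ∩ tumor = ∅`` exactly.
    """

    tumor: VOIMask
    dilated: VOIMask
    rim: VOIMask
    margin: float = field(default=3.0)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> CTVolume:
    """Read a 3D scalar NIfTI-1 file.

    Raises
    ------
    ValidationError
        If the image is not 3D scalar data.
    FileNotFoundError
        If the file does not exist.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"unsupported NIfTI data with ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return CTVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a :class:`CTVolume` (or the array of a mask) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(volume.intensities, dtype=np.float32),
                          volume.affine())
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: VOIMask, path) -> None:
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> VOIMask:
    vol = read_volume(path)
    return VOIMask((vol.intensities > 0.5).astype(np.uint8), vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(
    volume: CTVolume, mask: VOIMask | None, target: float = 1.0
) -> tuple[CTVolume, VOIMask | None]:
    """Resample a volume (trilinear) and its mask (nearest-neighbor) to an
    isotropic grid of ``target`` mm.

    The output grid covers the physical extent of the input grid: the number
    of output voxels per axis is ``ceil(n_in * spacing_in / target)``, and the
    origin is preserved.

    Parameters
    ----------
    volume : CTVolume
    mask : VOIMask or None
        Must share shape and spacing with `volume` when given.
    target : float
        Output voxel edge length in mm; must be positive.
    """
    if target <= 0:
        raise ValidationError(f"target spacing must be positive, got {target}")
    if mask is not None:
        if mask.shape != volume.shape:
            raise ValidationError("mask and volume shapes differ")
        if mask.spacing != volume.spacing:
            raise ValidationError("mask and volume spacings differ")

    in_spacing = np.array(volume.spacing)
    in_shape = np.array(volume.shape)
    out_shape = np.ceil(in_shape * in_spacing / target).astype(int)
    out_shape = np.maximum(out_shape, 1)

    # Map output voxel centers to input index space (voxel-center convention).
    grids = [
        (np.arange(n) * target) / sp for n, sp in zip(out_shape, in_spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack(coords)

    out_int = ndimage.map_coordinates(
        np.asarray(volume.intensities, dtype=np.float64),
        coords, order=1, mode="nearest",
    )
    out_vol = CTVolume(out_int, (target, target, target), volume.origin)

    out_mask = None
    if mask is not None:
        m = ndimage.map_coordinates(
            mask.data.astype(np.float32), coords, order=0, mode="constant", cval=0.0
        )
        out_mask = VOIMask((m > 0.5).astype(np.uint8),
                           (target, target, target), mask.origin)
    return out_vol, out_mask


# ---------------------------------------------------------------------------
# Rim geometry
# ---------------------------------------------------------------------------

def dilate_mask(mask: VOIMask, margin: float) -> VOIMask:
    """Metric dilation: add every voxel whose center lies within Euclidean
    distance ``margin`` (mm, physical units) of a foreground voxel center.

    Uses a Euclidean distance transform with the mask's physical spacing, so
    the margin is honoured on anisotropic grids as well.
    """
    if margin < 0:
        raise ValidationError(f"margin must be >= 0, got {margin}")
    if mask.count() == 0:
        raise EmptyMaskError("cannot dilate an empty mask")
    if margin == 0:
        return VOIMask(mask.data.copy(), mask.spacing, mask.origin)
    dist = ndimage.distance_transform_edt(
        mask.data == 0, sampling=mask.spacing
    )
    out = (dist <= margin + 1e-9).astype(np.uint8)
    return VOIMask(out, mask.spacing, mask.origin)


def make_regions(tumor: VOIMask, margin: float = 3.0) -> LesionRegions:
    """Build the tumor / dilated / rim mask triple for one lesion.

    ``rim`` is the dilated mask minus the tumor mask; it is the shell the
    peritumoral-rim features interrogate (rim features themselves are computed
    as dilated-region minus tumor-region feature differences downstream).
    """
    dilated = dilate_mask(tumor, margin)
    rim_data = (dilated.data.astype(np.int16) - tumor.data.astype(np.int16))
    rim = VOIMask(rim_data.astype(np.uint8), tumor.spacing, tumor.origin)
    if rim.count() == 0:
        warnings.warn("rim is empty: tumor reaches the grid boundary everywhere",
                      stacklevel=2)
        logger.warning("empty rim for margin=%s", margin)
    return LesionRegions(tumor=tumor, dilated=dilated, rim=rim, margin=float(margin))
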