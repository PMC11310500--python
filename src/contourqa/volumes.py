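"""Domain types for CT volumes and binary organ masks, plus NIfTI I/O.

Conventions (fixed for the whole package):

* 0-based voxel indices, axis order ``(x, y, z)`` matching the on-disk array;
* voxel-center physical coordinates: position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` in millimetres;
* images and masks must share a grid exactly — no resampling is ever
  performed, because contours are always compared on the same planning CT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ORGANS",
    "FormatError",
    "GeometryError",
    "VocabularyError",
    "ImageVolume",
    "BinaryMask",
    "BoxRegion",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: The closed 16-organ vocabulary used by the cranio-spinal contouring study.
ORGANS: tuple[str, ...] = (
    "brain",
    "brainstem",
    "chiasm",
    "cochlea_L",
    "cochlea_R",
    "esophagus",
    "eye_L",
    "eye_R",
    "lens_L",
    "lens_R",
    "lung_L",
    "lung_R",
    "kidney_L",
    "kidney_R",
    "optic_nerve_L",
    "optic_nerve_R",
)


class FormatError(ValueError):
    """A file is not a valid 3-D volume (wrong rank, bad spacing, ...)."""


class GeometryError(ValueError):
    """Two objects that must share a voxel grid do not."""


class VocabularyError(ValueError):
    """An organ label outside the known vocabulary where one is required."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D CT image: Hounsfield-unit voxels on a physical grid.

    Parameters
    ----------
    voxels:
        3-D array of HU values, axis order (x, y, z).
    spacing:
        Voxel size in mm per axis; all components must be positive.
    origin:
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"image must be 3-D, got {vox.ndim}-D")
        sp = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in sp):
            raise FormatError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class BinaryMask:
    """A boolean organ mask on an :class:`ImageVolume` grid.

    ``role`` distinguishes the clinician-approved ground truth from a test
    (auto-segmented) contour; for test contours it conventionally holds the
    method name (e.g. ``"atlas"``, ``"neural_network"``).  An empty mask is
    representable — consumers that cannot handle emptiness raise explicitly.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ: str = "brain"
    role: str = "ground_truth"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {vox.ndim}-D")
        if vox.dtype != bool:
            vox = vox > 0.5
        sp = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in sp):
            raise FormatError(f"spacing must be positive, got {sp}")
        if self.organ not in ORGANS:
            warnings.warn(
                f"organ {self.organ!r} is outside the 16-organ vocabulary",
                stacklevel=3,
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_positive(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def same_grid(self, other: "ImageVolume | BinaryMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned voxel-index box with inclusive bounds ``lo..hi``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("lo and hi must be 3-tuples")
        if any(a > b for a, b in zip(lo, hi)):
            raise ValueError(f"lo must be <= hi componentwise, got {lo} > {hi}")
        if any(a < 0 for a in lo):
            raise ValueError(f"lo must be nonnegative, got {lo}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def contains_grid(self, shape: tuple[int, int, int]) -> bool:
        return all(h < s for h, s in zip(self.hi, shape))

    @classmethod
    def full_grid(cls, shape: tuple[int, int, int]) -> "BoxRegion":
        return cls((0, 0, 0), tuple(s - 1 for s in shape))


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine is diagonal(spacing) with the origin as translation;
# no reorientation is attempted — the study compares contours on one CT, so
# every file in a cohort shares the grid by construction.
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI volume of HU values.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        If the file is not 3-D or declares non-positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected a 3-D volume, got {data.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path.name}: non-positive spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels=data, spacing=zooms, origin=origin)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI (dtype preserved)."""
    img = nib.Nifti1Image(volume.voxels, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    geometry: ImageVolume | BinaryMask | None = None,
    organ: str = "brain",
    role: str = "ground_truth",
    strict_organ: bool = False,
) -> BinaryMask:
    """Read a binary organ mask, optionally validated against a grid.

    Voxel values are thresholded at 0.5.  With *strict_organ* (the CLI
    boundary), unknown organ labels raise :class:`VocabularyError`; the
    programmatic default only warns, so the QA tool generalizes beyond the
    16-organ vocabulary.
    """
    if strict_organ and organ not in ORGANS:
        raise VocabularyError(f"unknown organ {organ!r}; expected one of {ORGANS}")
    vol = read_volume(path)
    if geometry is not None and not vol.same_grid(geometry):
        raise GeometryError(
            f"{Path(path).name}: mask grid {vol.shape}/{vol.spacing} does not "
            f"match geometry {geometry.shape}/{geometry.spacing}"
        )
    return BinaryMask(
        voxels=vol.voxels > 0.5,
        spacing=vol.spacing,
        origin=vol.origin,
        organ=organ,
        role=role,
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a :class:`BinaryMask` as uint8 NIfTI."""
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
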