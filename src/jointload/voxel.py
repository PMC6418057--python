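"""Isotropic 3-D voxel image container and MetaImage/NIfTI I/O.

Conventions used throughout the package:

* array axes are ordered ``(x, y, z)``;
* voxel *centres* sit at ``origin_mm + (index + 0.5) * spacing_mm``;
* spacing is isotropic and in millimetres.

SimpleITK handles the on-disk formats (``.mha``, ``.mhd``, ``.nii``,
``.nii.gz``); this module only translates between its ``(z, y, x)`` array
layout / centre-based origin and the package conventions above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelImage", "read_image", "write_image"]


@dataclass
class VoxelImage:
    """A 3-D scalar grid with isotropic spacing (mm) and a world origin.

    ``data`` may be grey-valued (float), binary (bool) or integer labels;
    the class is the carrier for all of them.
    """

    data: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing_mm = float(self.spacing_mm)
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("image data contains non-finite values")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise ValueError("origin_mm must be a 3-vector")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def voxel_centers_mm(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centres.

        With ``indices=None`` returns an ``(nx, ny, nz, 3)`` array; otherwise
        ``indices`` is an ``(m, 3)`` integer array and the result is ``(m, 3)``.
        """
        if indices is None:
            grids = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
            idx = np.stack(grids, axis=-1)
        else:
            idx = np.asarray(indices)
        return self.origin_mm + (idx + 0.5) * self.spacing_mm

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each world point (no bounds check)."""
        pts = np.asarray(points_mm, dtype=float)
        return np.floor((pts - self.origin_mm) / self.spacing_mm).astype(int)

    # -- convenience ------------------------------------------------------

    def astype(self, dtype) -> "VoxelImage":
        return replace(self, data=self.data.astype(dtype))

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.data.copy(), self.spacing_mm, self.origin_mm.copy())

    def is_binary(self) -> bool:
        return self.data.dtype == bool or set(np.unique(self.data)).issubset({0, 1})

    # -- I/O --------------------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.astype(np.float32).T))
        img.SetSpacing((self.spacing_mm,) * 3)
        # SimpleITK's origin is the centre of voxel (0,0,0)
        img.SetOrigin(tuple(self.origin_mm + 0.5 * self.spacing_mm))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VoxelImage":
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValueError(f"anisotropic spacing {spacing} is not supported")
        data = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
        origin = np.asarray(img.GetOrigin()) - 0.5 * spacing[0]
        return cls(np.ascontiguousarray(data), spacing[0], origin)

    def save(self, path: str | Path) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelImage":
        return cls.from_sitk(sitk.ReadImage(str(path)))


def read_image(path: str | Path) -> VoxelImage:
    """Read a MetaImage or NIfTI file into a :class:`VoxelImage`."""
    return VoxelImage.load(path)


def write_image(img: VoxelImage, path: str | Path) -> None:
    """Write a :class:`VoxelImage`; the format follows the file suffix."""
    img.save(path)
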