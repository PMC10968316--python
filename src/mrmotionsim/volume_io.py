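"""Volume container, NIfTI-1 I/O, intensity normalization and slice-window extraction.

The slice axis is always the third array axis (x, y, z); in-plane axis 0 is
treated as the phase-encode direction by the simulation stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "normalize_volume",
    "extract_center_slices",
]


@dataclass
class Volume:
    """A 3D scalar intensity array with voxel spacing.

    Parameters
    ----------
    data:
        3D array ``(x, y, z)``; ``z`` is the slice-stacking axis. Intensities
        must be finite, and nonnegative unless ``signed=True`` (signed volumes
        hold residual maps, which are differences of images).
    voxel_size:
        ``(dx, dy, dz)`` in millimetres.
    provenance:
        Free-form record of how this volume was derived (source path,
        extraction window, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)
    signed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if not self.signed and np.any(self.data < 0):
            raise ValueError("volume intensities must be nonnegative")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def get_slice(self, z: int) -> np.ndarray:
        """In-plane 2D slice at index ``z``."""
        if not 0 <= z < self.n_slices:
            raise IndexError(f"slice index {z} out of range [0, {self.n_slices})")
        return self.data[:, :, z]


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI-1 volume; the third axis is taken as the slice axis."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"could not read NIfTI volume {path!s}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path!s}: expected a 3D volume, got {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, voxel_size=tuple(float(z) for z in zooms),
                  provenance={"source": str(path)})


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from its voxel size."""
    affine = np.diag(list(v.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine)
    img.header.set_zooms(v.voxel_size)
    nib.save(img, str(path))


def normalize_volume(v: Volume) -> Volume:
    """Scale intensities so the volume maximum is exactly 1.0."""
    peak = float(np.max(v.data))
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero volume")
    return replace(v, data=v.data / peak,
                   provenance={**v.provenance, "normalized_by": peak})


def _auto_center_index(v: Volume) -> int:
    # CSF proxy: the slice with the largest area of very bright voxels.
    thresh = np.percentile(v.data, 95.0)
    areas = np.sum(v.data >= thresh, axis=(0, 1))
    return int(np.argmax(areas))


def extract_center_slices(
    v: Volume,
    n: int,
    center_index: Optional[int] = None,
    auto: bool = False,
) -> Volume:
    """Extract a contiguous ``n``-slice window centred on a reference slice.

    The window is ``[c - n//2, c - n//2 + n)``. When ``center_index`` is not
    given, ``c`` defaults to the volume's middle slice, or — with
    ``auto=True`` — to the slice with the largest bright (95th-percentile)
    area, a proxy for the CSF-filled lateral ventricles.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > v.n_slices:
        raise ValueError(f"cannot extract {n} slices from a {v.n_slices}-slice volume")
    if center_index is None:
        center_index = _auto_center_index(v) if auto else v.n_slices // 2
    start = int(center_index) - n // 2
    if start < 0 or start + n > v.n_slices:
        raise ValueError(
            f"window [{start}, {start + n}) centred at {center_index} "
            f"falls outside the {v.n_slices}-slice volume"
        )
    return Volume(
        data=v.data[:, :, start : start + n],
        voxel_size=v.voxel_size,
        provenance={**v.provenance, "center_index": int(center_index),
                    "window": (start, start + n)},
        signed=v.signed,
    )
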