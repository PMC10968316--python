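"""Synthetic brain-like phantoms: nested ellipsoidal tissue regions with known labels.

The default phantom stacks axial slices containing a dark background, an
outer gray-matter-like shell, an inner white-matter-like core, and a small
bright CSF-like region. Bright CSF-level signal is deliberately included:
high-intensity structures are what make motion ghosting visually and
quantitatively prominent in T2-weighted brain images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume

__all__ = ["TissueClass", "PhantomSpec", "LabeledVolume", "generate_phantom",
           "DEFAULT_TISSUE_CLASSES"]


class PhantomConfigError(ValueError):
    """Raised when a phantom specification describes impossible geometry."""


@dataclass(frozen=True)
class TissueClass:
    """One tissue compartment: an ellipsoid of roughly constant intensity.

    ``center`` and ``semiaxes`` are fractions of the volume extent along
    (x, y, z); ``center=None`` marks the background class, which fills
    everything not claimed by a later class.
    """

    name: str
    mean: float
    center: tuple[float, float, float] | None = None
    semiaxes: tuple[float, float, float] | None = None


# Painted in order; later (inner) classes overwrite earlier ones.
DEFAULT_TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass("background", 0.0),
    TissueClass("gray_matter", 0.6, center=(0.5, 0.5, 0.5), semiaxes=(0.42, 0.36, 0.44)),
    TissueClass("white_matter", 0.4, center=(0.5, 0.52, 0.5), semiaxes=(0.30, 0.25, 0.34)),
    TissueClass("csf", 0.95, center=(0.5, 0.45, 0.5), semiaxes=(0.10, 0.14, 0.20)),
)


@dataclass(frozen=True)
class PhantomSpec:
    matrix_size: int = 256
    n_slices: int = 68
    tissue_classes: tuple[TissueClass, ...] = DEFAULT_TISSUE_CLASSES
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 16:
            raise PhantomConfigError("matrix_size must be at least 16")
        if self.n_slices < 1:
            raise PhantomConfigError("n_slices must be at least 1")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be nonnegative")
        if not self.tissue_classes:
            raise PhantomConfigError("at least one tissue class (background) required")
        if self.tissue_classes[0].center is not None:
            raise PhantomConfigError("first tissue class must be the background (center=None)")
        if abs(self.tissue_classes[0].mean) > 0:
            raise PhantomConfigError("background mean intensity must be 0")
        for tc in self.tissue_classes:
            if not 0.0 <= tc.mean <= 1.0:
                raise PhantomConfigError(f"tissue mean {tc.mean} outside [0, 1] ({tc.name})")
            if (tc.center is None) != (tc.semiaxes is None):
                raise PhantomConfigError(f"class {tc.name}: center and semiaxes must be given together")
            if tc.center is not None:
                for c, a in zip(tc.center, tc.semiaxes):
                    if a <= 0:
                        raise PhantomConfigError(f"class {tc.name}: semiaxes must be positive")
                    if c - a < 0.0 or c + a > 1.0:
                        raise PhantomConfigError(
                            f"class {tc.name}: ellipsoid extends outside the volume"
                        )

    @property
    def class_means(self) -> np.ndarray:
        return np.array([tc.mean for tc in self.tissue_classes], dtype=np.float64)


@dataclass
class LabeledVolume:
    """A phantom volume together with its generating per-voxel tissue labels."""

    volume: Volume
    labels: np.ndarray  # int array, same shape; indexes spec.tissue_classes
    class_means: np.ndarray

    def __post_init__(self) -> None:
        if self.volume.shape != self.labels.shape:
            raise ValueError("volume and labels must share one shape")


def _fractional_grid(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    # Voxel-centre coordinates in [0, 1] along each axis.
    return tuple(
        ((np.arange(n) + 0.5) / n).reshape([-1 if i == ax else 1 for i in range(3)])
        for ax, n in enumerate(shape)
    )


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Generate a labelled phantom volume.

    Voxel intensity = class mean + N(0, noise_sd), clipped to [0, 1].
    Deterministic for a fixed spec (including seed).
    """
    shape = (spec.matrix_size, spec.matrix_size, spec.n_slices)
    fx, fy, fz = _fractional_grid(shape)

    labels = np.zeros(shape, dtype=np.int16)
    for idx, tc in enumerate(spec.tissue_classes):
        if tc.center is None:
            continue
        (cx, cy, cz), (ax, ay, az) = tc.center, tc.semiaxes
        inside = ((fx - cx) / ax) ** 2 + ((fy - cy) / ay) ** 2 + ((fz - cz) / az) ** 2 <= 1.0
        labels[inside] = idx

    data = spec.class_means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    data = np.clip(data, 0.0, 1.0)

    vol = Volume(data=data, voxel_size=(1.0, 1.0, 1.0),
                 provenance={"phantom_seed": spec.seed})
    return LabeledVolume(volume=vol, labels=labels, class_means=spec.class_means)
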