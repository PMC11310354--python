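"""Core domain containers shared by every strainkit module.

Array convention (used everywhere, asserted in tests): 0-based, origin at
the top-left, axis 0 = depth (y, superficial tissue at low row indices),
axis 1 = longitudinal (x).  Strains are dimensionless; displacements are
in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ImageSequence",
    "TendonGeometry",
    "StrainField",
    "DisplacementField",
    "DeformationClass",
    "TENSION",
    "COMPRESSION",
    "RIGID",
    "CLASS_NAMES",
    "SyntheticSample",
    "TestCase",
    "LoadProtocol",
]

CLASS_NAMES = ("tension", "compression", "rigid")


@dataclass(frozen=True)
class DeformationClass:
    """One of the three bulk deformation modes an image pair can undergo."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ValueError(f"unknown deformation class {self.label!r}")

    @property
    def index(self) -> int:
        return CLASS_NAMES.index(self.label)

    @classmethod
    def from_index(cls, index: int) -> "DeformationClass":
        return cls(CLASS_NAMES[index])


TENSION = DeformationClass("tension")
COMPRESSION = DeformationClass("compression")
RIGID = DeformationClass("rigid")


@dataclass
class ImageSequence:
    """An ordered stack of grayscale frames with physical metadata.

    ``frames`` is a list of (H, W) float arrays with intensities in [0, 1];
    ``pixel_spacing`` is mm per pixel (isotropic) and ``frame_interval``
    the time between consecutive frames in seconds.
    """

    frames: list[np.ndarray]
    pixel_spacing: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("an image sequence needs at least two frames")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(f)):
                raise ValueError(f"frame {i} contains non-finite values")
        if self.pixel_spacing <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_spacing and frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, in seconds, starting at 0."""
        return np.arange(len(self.frames)) * self.frame_interval


@dataclass
class TendonGeometry:
    """Location and orientation of the tendon within the image.

    ``tendon_mask`` flags tendon pixels; ``depth_axis`` is the image axis
    running superficial -> deep (0 = rows); ``long_axis`` is the
    longitudinal axis (1 = columns); ``superficial_ratio`` scales the
    longitudinal strain at the superficial edge relative to the deep edge.
    """

    tendon_mask: np.ndarray
    depth_axis: int = 0
    long_axis: int = 1
    superficial_ratio: float = 0.75

    def __post_init__(self) -> None:
        self.tendon_mask = np.asarray(self.tendon_mask, dtype=bool)
        if self.tendon_mask.ndim != 2 or not self.tendon_mask.any():
            raise ValueError("tendon_mask must be a non-empty 2-D mask")
        if {self.depth_axis, self.long_axis} != {0, 1}:
            raise ValueError("depth_axis and long_axis must be {0, 1}")
        if not 0.0 < self.superficial_ratio <= 1.0:
            raise ValueError("superficial_ratio must lie in (0, 1]")

    @property
    def depth_extent(self) -> tuple[int, int]:
        """First and last tendon row along the depth axis (inclusive)."""
        rows = np.where(self.tendon_mask.any(axis=self.long_axis))[0]
        return int(rows[0]), int(rows[-1])


@dataclass
class StrainField:
    """Per-pixel symmetric 2-D strain tensor (exx, exy, eyy) + validity."""

    exx: np.ndarray
    exy: np.ndarray
    eyy: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.exx = np.asarray(self.exx, dtype=float)
        self.exy = np.asarray(self.exy, dtype=float)
        self.eyy = np.asarray(self.eyy, dtype=float)
        if not (self.exx.shape == self.exy.shape == self.eyy.shape):
            raise ValueError("strain components must share one shape")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.exx.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.exx.shape:
                raise ValueError("valid_mask shape mismatch")
        for name in ("exx", "exy", "eyy"):
            comp = getattr(self, name)
            if not np.all(np.isfinite(comp[self.valid_mask])):
                raise ValueError(f"{name} non-finite on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.exx.shape

    def channels(self) -> np.ndarray:
        """Stack the three stored components as a (3, H, W) array."""
        return np.stack([self.exx, self.exy, self.eyy])

    def tensor(self) -> np.ndarray:
        """Expand to the full symmetric tensor, shape (H, W, 2, 2)."""
        t = np.empty(self.exx.shape + (2, 2))
        t[..., 0, 0] = self.exx
        t[..., 0, 1] = self.exy
        t[..., 1, 0] = self.exy
        t[..., 1, 1] = self.eyy
        return t

    @classmethod
    def from_channels(
        cls, channels: np.ndarray, valid_mask: np.ndarray | None = None
    ) -> "StrainField":
        if channels.shape[0] != 3:
            raise ValueError("expected a (3, H, W) channel stack")
        return cls(channels[0], channels[1], channels[2], valid_mask)

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "StrainField":
        z = np.zeros(shape)
        return cls(z, z.copy(), z.copy())


@dataclass
class DisplacementField:
    """Pixel displacements: u along the longitudinal axis, v along depth."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of one shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacements must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass
class SyntheticSample:
    """One training example: an image pair with exact ground truth."""

    image_ref: np.ndarray
    image_def: np.ndarray
    truth: StrainField
    cls: DeformationClass
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class LoadProtocol:
    """Timing of one contraction cycle: ramp up, hold, relax (seconds)."""

    ramp_s: float = 3.0
    hold_s: float = 5.0
    relax_s: float = 3.0

    def __post_init__(self) -> None:
        if min(self.ramp_s, self.hold_s, self.relax_s) <= 0:
            raise ValueError("protocol phases must be positive")

    @property
    def duration(self) -> float:
        return self.ramp_s + self.hold_s + self.relax_s


@dataclass
class TestCase:
    """A benchmark sequence with per-frame ground truth vs. frame 1."""

    sequence: ImageSequence
    truths: list[StrainField]
    eps_long_max: float
    protocol: LoadProtocol = LoadProtocol()

    def __post_init__(self) -> None:
        if len(self.truths) != len(self.sequence) - 1:
            raise ValueError("need one ground-truth field per frame pair")
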