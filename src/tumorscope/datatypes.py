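"""Core data containers shared across the pipeline.

Conventions used throughout the package (stated once, here):

* pixel coordinates are 0-based, row-major ``(y, x)``;
* bounding boxes are half-open: ``[x_min, x_max) x [y_min, y_max)`` in pixel
  units, so a single-pixel box at the origin is ``(0, 0, 1, 1)``;
* mask label 1 marks lung tissue (the minority class), label 0 everything
  else (the majority class);
* slice stacks are ordered by ``slice_index`` along the cranio-caudal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SliceImage", "MaskImage", "TumorAnnotation", "VoxelVolume",
    "PhantomCase", "PhantomConfig",
]


@dataclass
class SliceImage:
    """One grayscale CT slice with intensities normalised to [0, 1]."""

    pixels: np.ndarray
    case_id: str = "case"
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.slice_index < 0:
            raise ValueError("slice_index must be nonnegative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MaskImage:
    """Binary pixel labelling; 1 = lung (minority), 0 = non-lung (majority)."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask labels must be exactly 0 or 1")
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def lung_fraction(self) -> float:
        """Share of pixels labelled lung; < 0.5 for any valid phantom."""
        return float(self.labels.mean())


@dataclass
class TumorAnnotation:
    """Axis-aligned nodule bounding box on one slice (half-open box)."""

    slice_index: int
    box: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    nodule_id: str = "nodule-0"

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")

    def validate_bounds(self, height: int, width: int) -> None:
        x0, y0, x1, y1 = self.box
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
            raise ValueError(f"box {self.box} outside {height}x{width} image")


@dataclass
class VoxelVolume:
    """3-D occupancy grid in [0, 1]; axis order (depth, height, width)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxel values must be finite")
        if self.voxels.min() < 0.0 or self.voxels.max() > 1.0:
            raise ValueError("voxel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        return (self.voxels >= threshold).astype(np.uint8)


@dataclass
class PhantomCase:
    """One synthetic patient: slice stack, masks, boxes and the 3-D tumor."""

    slices: list[SliceImage]
    masks: list[MaskImage]
    annotations: list[TumorAnnotation]
    tumor_volume: VoxelVolume
    seed: int = 0

    def __post_init__(self):
        if len(self.slices) != len(self.masks):
            raise ValueError("slices and masks must pair one-to-one")
        n = len(self.slices)
        indices = [s.slice_index for s in self.slices]
        if len(set(indices)) != n:
            raise ValueError("slice_index values must be unique within a case")
        if self.tumor_volume.shape[0] != n:
            raise ValueError("tumor volume depth must equal slice count")
        for ann in self.annotations:
            if ann.slice_index not in set(indices):
                raise ValueError(f"annotation on unknown slice {ann.slice_index}")
            s = self.slices[0]
            ann.validate_bounds(s.height, s.width)

    @property
    def case_id(self) -> str:
        return self.slices[0].case_id

    def has_nodule(self) -> bool:
        return len(self.annotations) > 0


@dataclass
class PhantomConfig:
    """Generation knobs for synthetic patients.

    `lung_fraction_range` must sit inside (0, 0.5): lung tissue is always the
    minority class, which is the imbalance the segmentation stage exists to
    handle.
    """

    image_size: int = 32
    n_slices: int = 6
    lung_fraction_range: tuple[float, float] = (0.08, 0.18)
    n_nodules_range: tuple[int, int] = (1, 2)
    nodule_radius_range: tuple[float, float] = (1.5, 3.0)
    noise_sd: float = 0.03
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        lo, hi = self.lung_fraction_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("lung_fraction_range must sit inside (0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        n_lo, n_hi = self.n_nodules_range
        if n_lo < 0 or n_hi < n_lo:
            raise ValueError("invalid n_nodules_range")
        r_lo, r_hi = self.nodule_radius_range
        if r_lo <= 0 or r_hi < r_lo:
            raise ValueError("invalid nodule_radius_range")
        if r_hi > self.image_size / 4:
            raise ValueError(
                "nodule radius exceeds plausible lung extent for this image size")
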