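"""Core data types shared by every pipeline stage.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``; row 0 is the top image row;
* intensities are floats in ``[0, 1]`` internally (8-bit I/O at the boundary);
* binary masks are plain boolean :class:`numpy.ndarray` objects with the same
  shape as the frame they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GrayFrame",
    "PointSet",
    "LabeledRegions",
    "DensityMap",
    "ColonyMask",
    "FlowField",
    "SpeedSummary",
    "PipelineConfig",
]


@dataclass
class GrayFrame:
    """One 2-D grayscale frame with acquisition metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities in ``[0, 1]``.
    frame_index
        Position of the frame in its time series (0-based).
    interval_min
        Minutes between consecutive frames of the series.
    pixel_size_um
        Micrometres per pixel; ``None`` when the camera/objective
        combination is unknown (speeds are then reported in px/frame).
    """

    pixels: np.ndarray
    frame_index: int = 0
    interval_min: float = 5.0
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("pixels must be 2-D with at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be > 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


POINT_KINDS = ("nucleolus", "branch_point", "pooled")


@dataclass
class PointSet:
    """Pixel coordinates of detected landmarks of one class.

    ``points`` is an ``(n, 2)`` integer array of ``(row, col)`` pairs.
    Duplicate coordinates are forbidden within a single-kind set; a
    ``"pooled"`` set may contain the same coordinate once per source kind,
    because each occurrence contributes kernel mass to the density estimate.
    """

    points: np.ndarray
    kind: str
    frame_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if self.kind not in POINT_KINDS:
            raise ValueError(f"kind must be one of {POINT_KINDS}")
        if self.frame_shape is not None and len(pts):
            r, c = pts[:, 0], pts[:, 1]
            if (r.min() < 0 or c.min() < 0 or r.max() >= self.frame_shape[0]
                    or c.max() >= self.frame_shape[1]):
                raise ValueError("points fall outside the source image bounds")
        if self.kind != "pooled" and len(pts) != len({tuple(p) for p in pts}):
            raise ValueError("duplicate coordinates in a single-kind PointSet")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LabeledRegions:
    """Connected components of a binary mask.

    ``label_image`` holds 0 for background and consecutive ids 1..K assigned
    in raster order of each region's first-encountered pixel.  ``areas`` and
    ``centroids`` are indexed so that entry ``k - 1`` describes label ``k``.
    """

    label_image: np.ndarray
    areas: np.ndarray          # (K,) int
    centroids: np.ndarray      # (K, 2) float, (row, col)

    @property
    def n_regions(self) -> int:
        return len(self.areas)


@dataclass
class DensityMap:
    """Per-pixel kernel density surface over a landmark point set."""

    values: np.ndarray
    bandwidth: float
    n_points: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")


@dataclass
class ColonyMask:
    """Binary colony membership for one frame (single largest KDE region)."""

    pixels: np.ndarray
    frame_index: int = 0
    empty_reason: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass
class FlowField:
    """Dense displacement field between two consecutive frames.

    ``u`` is the column (x) displacement and ``v`` the row (y) displacement,
    in pixels per frame interval, such that content at ``(r, c)`` in frame t
    appears at ``(r + v, c + u)`` in frame t+1.
    """

    u: np.ndarray
    v: np.ndarray
    frame_pair: tuple[int, int] = (0, 1)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share one shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class SpeedSummary:
    """Colony locomotion speed aggregated over consecutive frame pairs."""

    per_pair_means: list[float]
    mean_speed: float
    sd_speed: Optional[float]      # None when < 2 usable pairs
    n_pixels: int
    unit: str                      # "um/min" or "px/frame"
    colony_id: str = ""
    condition_label: str = ""
    skipped_pairs: list[tuple[int, int]] = field(default_factory=list)


_DEFAULT = object()


@dataclass
class PipelineConfig:
    """Every tunable of the extraction/flow pipeline in one auditable place.

    Defaults follow the published procedure where it states a value:
    41×41 adaptive-threshold neighborhood, nucleolus size range [12, 72] px,
    removal of boundary regions of <= 250 px, Gaussian KDE bandwidth 151 px,
    and a 5-minute frame interval.
    """

    binarize_window: int = 41
    binarize_offset: float = 0.03          # fraction of intensity range
    binarize_method: str = "gaussian"      # "gaussian" | "box" local mean
    nucleolus_min_px: int = 12
    nucleolus_max_px: int = 72
    boundary_min_region_px: int = 250      # regions of this size or smaller removed
    kde_bandwidth: float = 151.0
    kde_threshold_frac: float = 0.2
    kde_boundary: str = "reflect"          # "reflect" | "none"
    kde_threshold_abs: Optional[float] = None   # overrides the relative rule
    connectivity: int = 8
    include_crossings: bool = False        # also count CN==4 pixels as branch points
    flow_backend: str = "ilk"
    block_size: int = 16
    search_radius: int = 5
    pixel_size_um: Optional[float] = None
    interval_min: float = 5.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.binarize_window < 3 or self.binarize_window % 2 == 0:
            raise ValueError("binarize_window must be odd and >= 3")
        if self.nucleolus_min_px > self.nucleolus_max_px:
            raise ValueError("nucleolus_min_px must be <= nucleolus_max_px")
        if self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be > 0")
        if not (self.kde_threshold_abs is not None or 0 < self.kde_threshold_frac < 1):
            raise ValueError("kde_threshold_frac must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.binarize_method not in ("gaussian", "box"):
            raise ValueError("binarize_method must be 'gaussian' or 'box'")
        if self.kde_boundary not in ("reflect", "none"):
            raise ValueError("kde_boundary must be 'reflect' or 'none'")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
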