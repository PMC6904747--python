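"""Synthetic phase-contrast scenes with known ground truth.

The generator emulates the contrast structure the pipeline consumes, not
photorealism: keratinocyte colonies are densely packed cells whose nucleoli
appear as dark spots inside dark nuclear rings, separated by a bright
cell-cell boundary mesh; the surrounding feeder layer holds sparse dark
elongated fibroblasts and no mesh.  Decoy dark spots without rings are
scattered outside the colony — the false-positive class the nuclear-ring
enclosure rule must reject.

Cells are seeded on a jittered grid inside the colony polygon; the mesh is
the boundary of the induced nearest-seed partition.  Motion (rigid
translation or radial expansion) is applied to the pre-noise scene by
recursive bilinear warping, so warping frame t with the ground-truth field
reproduces frame t+1 exactly before noise; fresh Gaussian noise is added
per frame (flow must track structure, not noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon2mask

from .model import GrayFrame, PointSet

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "scene_suite",
           "SCENE_PROFILES"]

# intensity palette (float [0,1]); chosen so every structure clears the
# default adaptive-threshold offset of 0.03 with a wide margin
BG = 0.55
NUCLEOLUS_DROP = 0.40        # nucleolus = BG - nucleus_darkness - extra drop


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic time-lapse scene."""

    shape: tuple[int, int] = (512, 512)
    colony_polygon: Optional[np.ndarray] = None   # (k, 2) (row, col); None = no colony
    n_cells: Optional[int] = None                 # None = fill polygon at cell_size
    cell_size_px: float = 24.0                    # mean seed spacing
    nucleolus_radius_px: float = 3.0
    ring_radius_px: float = 8.0                   # outer radius; thickness 2 px
    boundary_brightness: float = 0.35
    nucleus_darkness: float = 0.25
    n_feeder: int = 20
    n_decoys: int = 6                             # naked dark spots, no ring
    noise_sd: float = 0.01
    motion: tuple = ("zero",)                     # ("zero",) | ("translation",(dv,du))
                                                  # | ("radial", rate_px_per_frame)
    n_frames: int = 1
    seed: int = 0
    interval_min: float = 5.0
    pixel_size_um: Optional[float] = None
    condition: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.colony_polygon is not None:
            poly = np.asarray(self.colony_polygon, dtype=float)
            if (poly.min() < 0 or poly[:, 0].max() >= self.shape[0]
                    or poly[:, 1].max() >= self.shape[1]):
                raise ValueError("colony_polygon exceeds image bounds")
            self.colony_polygon = poly


@dataclass
class GroundTruth:
    """Known truth accompanying a generated scene."""

    colony_masks: list[np.ndarray]           # per frame
    nucleoli: list[PointSet]                 # per frame
    flow_fields: list[tuple[np.ndarray, np.ndarray]]   # (v, u) per frame pair
    feeder_centroids: np.ndarray             # (m, 2)
    prenoise_frames: list[np.ndarray]        # for warp-consistency checks


def regular_polygon(center: tuple[float, float], radius: float, k: int = 8,
                    radial_jitter: np.ndarray | None = None) -> np.ndarray:
    """Vertices of a k-gon (optionally radially jittered), (row, col)."""
    ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
    rad = radius * (1.0 + (radial_jitter if radial_jitter is not None else 0.0))
    return np.column_stack([center[0] + rad * np.sin(ang),
                            center[1] + rad * np.cos(ang)])


def _place_seeds(polygon_mask: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid cell seeds, kept clear of the polygon edge."""
    margin = spec.ring_radius_px + 3
    interior = ndimage.distance_transform_edt(polygon_mask) > margin
    s = spec.cell_size_px
    rr = np.arange(s / 2, polygon_mask.shape[0], s)
    cc = np.arange(s / 2, polygon_mask.shape[1], s)
    grid = np.array([(r, c) for r in rr for c in cc])
    jitter = rng.uniform(-s / 12, s / 12, size=grid.shape)
    pts = np.round(grid + jitter).astype(int)
    pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < polygon_mask.shape[0])
              & (pts[:, 1] >= 0) & (pts[:, 1] < polygon_mask.shape[1])]
    pts = pts[interior[pts[:, 0], pts[:, 1]]]
    if spec.n_cells is not None:
        if len(pts) < spec.n_cells:
            raise ValueError(
                f"colony polygon too small for n_cells={spec.n_cells} "
                f"(room for {len(pts)} at cell_size {s})")
        pts = pts[rng.choice(len(pts), spec.n_cells, replace=False)]
        pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    return pts


def _paint_colony(base: np.ndarray, polygon_mask: np.ndarray,
                  seeds: np.ndarray, spec: SceneSpec) -> None:
    """Draw mesh, nuclear rings and nucleoli in place."""
    if len(seeds) == 0:
        return
    shape = base.shape
    seed_img = np.ones(shape, dtype=bool)
    seed_img[seeds[:, 0], seeds[:, 1]] = False
    dist, (ir, ic) = ndimage.distance_transform_edt(seed_img, return_indices=True)
    owner = ir.astype(np.int64) * shape[1] + ic   # nearest-seed partition id

    mesh = np.zeros(shape, dtype=bool)
    mesh[:-1, :] |= owner[:-1, :] != owner[1:, :]
    mesh[:, :-1] |= owner[:, :-1] != owner[:, 1:]
    mesh = ndimage.binary_dilation(mesh, structure=np.ones((3, 3), bool))
    mesh &= polygon_mask
    base[mesh] = BG + spec.boundary_brightness

    ring = (dist >= spec.ring_radius_px - 2) & (dist < spec.ring_radius_px)
    base[ring & polygon_mask] = BG - spec.nucleus_darkness
    spot = dist < spec.nucleolus_radius_px
    base[spot & polygon_mask] = max(BG - spec.nucleus_darkness - NUCLEOLUS_DROP,
                                    0.02)


def _paint_feeders(base: np.ndarray, polygon_mask: np.ndarray, spec: SceneSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Sparse dark elongated feeder cells plus naked decoy spots outside."""
    shape = base.shape
    outside = ~ndimage.binary_dilation(polygon_mask, iterations=15) \
        if polygon_mask.any() else np.ones(shape, bool)
    # stay clear of the border so ellipses stay in frame
    outside[:15, :] = outside[-15:, :] = False
    outside[:, :15] = outside[:, -15:] = False
    cand = np.argwhere(outside)
    centers = np.zeros((0, 2), int)
    if len(cand) and spec.n_feeder > 0:
        centers = cand[rng.choice(len(cand), min(spec.n_feeder, len(cand)),
                                  replace=False)]
        for r, c in centers:
            rr, cc = draw_ellipse(r, c, 3, 12, shape=shape,
                                  rotation=rng.uniform(0, np.pi))
            base[rr, cc] = BG - spec.nucleus_darkness
    if len(cand) and spec.n_decoys > 0:
        decoys = cand[rng.choice(len(cand), min(spec.n_decoys, len(cand)),
                                 replace=False)]
        for r, c in decoys:
            rr, cc = draw_ellipse(r, c, spec.nucleolus_radius_px,
                                  spec.nucleolus_radius_px, shape=shape)
            base[rr, cc] = max(BG - spec.nucleus_darkness - NUCLEOLUS_DROP, 0.02)
    return centers


def _motion_field(spec: SceneSpec, shape: tuple[int, int]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ground-truth displacement (v, u) for one frame step."""
    kind = spec.motion[0]
    if kind == "zero":
        z = np.zeros(shape)
        return z, z.copy()
    if kind == "translation":
        dv, du = spec.motion[1]
        return np.full(shape, float(dv)), np.full(shape, float(du))
    if kind == "radial":
        rate = float(spec.motion[1])
        r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        rr = np.arange(shape[0])[:, None] - r0
        cc = np.arange(shape[1])[None, :] - c0
        norm = np.maximum(np.hypot(rr, cc), 1e-9)
        return rate * rr / norm, rate * cc / norm
    raise ValueError(f"unknown motion kind {spec.motion!r}")


def _warp(img: np.ndarray, v: np.ndarray, u: np.ndarray, order: int) -> np.ndarray:
    """Pull-back warp: out(x) = img(x - d(x)) with bilinear resampling."""
    rr, cc = np.meshgrid(np.arange(img.shape[0], dtype=float),
                         np.arange(img.shape[1], dtype=float), indexing="ij")
    return ndimage.map_coordinates(img.astype(float), [rr - v, cc - u],
                                   order=order, mode="nearest")


def generate_scene(spec: SceneSpec) -> tuple[list[GrayFrame], GroundTruth]:
    """Render the scene and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    polygon_mask = (polygon2mask(shape, spec.colony_polygon)
                    if spec.colony_polygon is not None
                    else np.zeros(shape, dtype=bool))
    base = np.full(shape, BG)
    seeds = (_place_seeds(polygon_mask, spec, rng)
             if polygon_mask.any() and (spec.n_cells is None or spec.n_cells > 0)
             else np.zeros((0, 2), int))
    _paint_colony(base, polygon_mask, seeds, spec)
    feeders = _paint_feeders(base, polygon_mask, spec, rng)

    v, u = _motion_field(spec, shape)
    prenoise = [base]
    masks = [polygon_mask]
    points = [seeds]
    flows: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(spec.n_frames - 1):
        prenoise.append(_warp(prenoise[-1], v, u, order=1))
        masks.append(_warp(masks[-1].astype(float), v, u, order=0) > 0.5)
        pts = points[-1].astype(float) + np.column_stack(
            [v[points[-1][:, 0], points[-1][:, 1]],
             u[points[-1][:, 0], points[-1][:, 1]]]) if len(points[-1]) else \
            points[-1].astype(float)
        points.append(np.round(pts).astype(int))
        flows.append((v, u))

    frames = []
    for i, pre in enumerate(prenoise):
        noisy = np.clip(pre + rng.normal(0.0, spec.noise_sd, shape), 0.0, 1.0) \
            if spec.noise_sd > 0 else pre
        frames.append(GrayFrame(noisy, frame_index=i,
                                interval_min=spec.interval_min,
                                pixel_size_um=spec.pixel_size_um))

    truth_points = []
    for pts in points:
        if len(pts):
            pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < shape[0])
                      & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])]
            pts = np.unique(pts, axis=0)
        truth_points.append(PointSet(pts.reshape(-1, 2), "nucleolus", shape))
    truth = GroundTruth(colony_masks=masks, nucleoli=truth_points,
                        flow_fields=flows, feeder_centroids=feeders,
                        prenoise_frames=prenoise)
    return frames, truth


# ---------------------------------------------------------------------------
# canonical scene suites

SCENE_PROFILES = ("segmentation", "flow", "screening")

# Segmentation scenes are full microscope fields: with the default KDE
# bandwidth (151 px) the density contour at 0.2 x max sits ~0.85 bandwidths
# outside the true colony edge, so the colony must be large relative to the
# bandwidth (radius ~2.5 h) and the field large relative to that ring for
# pixel accuracy to be meaningful at all.
_SEG_SHAPE = (2304, 2304)
_SEG_RADIUS = 380.0


def scene_suite(profile: str, master_seed: int = 0) -> list[SceneSpec]:
    """Canonical scene lists for the three evaluation profiles.

    ``segmentation``: 10 single-frame fields varying cell density and feeder
    count.  ``flow``: pure translations (including sub-pixel amplitudes
    0.5/1/2 px per frame on a 3-4-5 direction) plus one radial-expansion
    scene.  ``screening``: 5 "control" colonies moving 2 px/frame vs 5
    "inhibited" colonies at 0.1 px/frame, three frames each — the layout of
    a two-condition inhibitor experiment.
    """
    rng = np.random.default_rng(master_seed)
    if profile == "segmentation":
        specs = []
        for i in range(10):
            jit = rng.uniform(-0.12, 0.12, 8)
            center = (_SEG_SHAPE[0] / 2 + rng.uniform(-80, 80),
                      _SEG_SHAPE[1] / 2 + rng.uniform(-80, 80))
            specs.append(SceneSpec(
                shape=_SEG_SHAPE,
                colony_polygon=regular_polygon(center, _SEG_RADIUS, 8, jit),
                cell_size_px=float(22 + 2 * (i % 4)),
                n_feeder=60 + 20 * i,
                n_decoys=8 + 2 * i,
                noise_sd=0.01,
                n_frames=1,
                seed=int(rng.integers(2 ** 31)),
                name=f"segmentation-{i}",
            ))
        return specs
    if profile == "flow":
        motions = [
            ("translation", (0.0, 0.0)),
            ("translation", (0.0, 3.0)),
            ("translation", (-2.0, 1.0)),
            ("translation", (0.3, 0.4)),     # amplitude 0.5 px/frame
            ("translation", (0.6, 0.8)),     # amplitude 1
            ("translation", (1.2, 1.6)),     # amplitude 2
            ("radial", 1.0),
        ]
        return [
            SceneSpec(
                shape=(256, 256),
                colony_polygon=regular_polygon((128, 128), 80.0, 8,
                                               rng.uniform(-0.1, 0.1, 8)),
                cell_size_px=22.0,
                n_feeder=6, n_decoys=3, noise_sd=0.005,
                motion=m, n_frames=3,
                seed=int(rng.integers(2 ** 31)),
                name=f"flow-{j}",
            )
            for j, m in enumerate(motions)
        ]
    if profile == "screening":
        specs = []
        for cond, (dv, du) in (("control", (1.2, 1.6)),
                               ("inhibited", (0.06, 0.08))):
            for k in range(5):
                jit = rng.uniform(-0.1, 0.1, 8)
                specs.append(SceneSpec(
                    shape=(512, 512),
                    colony_polygon=regular_polygon((256, 256), 150.0, 8, jit),
                    cell_size_px=24.0,
                    n_feeder=15, n_decoys=5, noise_sd=0.005,
                    motion=("translation", (dv, du)),
                    n_frames=3,
                    seed=int(rng.integers(2 ** 31)),
                    condition=cond,
                    name=f"{cond}-{k}",
                ))
        return specs
    raise ValueError(
        f"unknown profile {profile!r}; available: {', '.join(SCENE_PROFILES)}")
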