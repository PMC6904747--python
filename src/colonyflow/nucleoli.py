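"""Nucleolus detection — procedure (1) of the colony-extraction pipeline.

In phase contrast the nucleolus of a keratinocyte appears as a dark spot and
the nucleus as a dark ring around it.  Adaptive binarization against a local
weighted mean highlights both; connected components in the size range
[12, 72] px whose centroid lies in their own region AND which sit inside a
hole of another dark region (the nuclear ring) are accepted as nucleoli.
Dark debris and feeder-cell fragments lack the enclosing ring and are
rejected — they are the classic false-positive class of this assay.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import GrayFrame, LabeledRegions, PipelineConfig, PointSet

__all__ = [
    "adaptive_binarize",
    "label_components",
    "filter_by_size",
    "detect_nucleoli",
]

_STRUCT = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def adaptive_binarize(
    frame: GrayFrame | np.ndarray,
    window: int = 41,
    offset: float = 0.03,
    polarity: str = "dark",
    method: str = "gaussian",
) -> np.ndarray:
    """Threshold each pixel against a weighted mean of its neighborhood.

    ``polarity="dark"`` marks pixels strictly below ``local_mean - offset``,
    ``"bright"`` those strictly above ``local_mean + offset``.  The weighted
    mean is Gaussian (sigma = window/6, support clipped to the window) by
    default, or a plain box mean with ``method="box"``.  Borders use
    reflected padding.
    """
    arr = frame.pixels if isinstance(frame, GrayFrame) else np.asarray(frame, float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window >= min(arr.shape):
        raise ValueError("window must be smaller than both image dimensions")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")

    if method == "gaussian":
        sigma = window / 6.0
        radius = window // 2
        local = ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect",
                                        truncate=radius / sigma)
    elif method == "box":
        local = ndimage.uniform_filter(arr, size=window, mode="reflect")
    else:
        raise ValueError("method must be 'gaussian' or 'box'")

    if polarity == "dark":
        return arr < local - offset
    return arr > local + offset


def _relabel_raster(label_image: np.ndarray) -> np.ndarray:
    """Remap labels to consecutive 1..K in raster order of first pixel."""
    flat = label_image.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return label_image
    seen = flat[nz]
    # order of first occurrence
    _, first_idx = np.unique(seen, return_index=True)
    order = seen[np.sort(first_idx)]
    mapping = np.zeros(label_image.max() + 1, dtype=label_image.dtype)
    mapping[order] = np.arange(1, len(order) + 1)
    return mapping[label_image]


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Maximal connected components with deterministic raster label order."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_STRUCT[connectivity])
    lab = _relabel_raster(lab)
    if n == 0:
        return LabeledRegions(lab, np.zeros(0, int), np.zeros((0, 2)))
    areas = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    idx = np.arange(1, n + 1)
    centroids = np.array(ndimage.center_of_mass(mask, lab, idx), dtype=float)
    return LabeledRegions(lab, areas.astype(int), centroids)


def filter_by_size(regions: LabeledRegions, min_px: int, max_px: int) -> LabeledRegions:
    """Keep regions with ``min_px <= area <= max_px``; relabel 1..K."""
    if min_px > max_px:
        raise ValueError("min_px must be <= max_px")
    keep = (regions.areas >= min_px) & (regions.areas <= max_px)
    kept_labels = np.flatnonzero(keep) + 1
    mapping = np.zeros(regions.n_regions + 1, dtype=regions.label_image.dtype)
    mapping[kept_labels] = np.arange(1, len(kept_labels) + 1)
    return LabeledRegions(
        mapping[regions.label_image],
        regions.areas[keep],
        regions.centroids[keep],
    )


def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Nearest integer with .5 ties toward the smaller index (determinism)."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def enclosed_labels(mask: np.ndarray, label_image: np.ndarray) -> np.ndarray:
    """Boolean flag per label: is the region inside a hole of other foreground?

    A region is *enclosed* when every background-connected path (4-connected
    background, the topological dual of 8-connected foreground) from it to
    the image border crosses foreground that is not the region itself.
    Computed globally: background components touching the border are
    "outside"; a region adjacent to outside background, or touching the
    border itself, is not enclosed.
    """
    n = int(label_image.max())
    if n == 0:
        return np.zeros(0, dtype=bool)
    bg = ~np.asarray(mask, dtype=bool)
    bg_lab, _ = ndimage.label(bg, structure=_STRUCT[4])
    border_bg = np.unique(
        np.concatenate([bg_lab[0, :], bg_lab[-1, :], bg_lab[:, 0], bg_lab[:, -1]])
    )
    outside = np.isin(bg_lab, border_bg[border_bg > 0])
    # labels 4-adjacent to outside background, or on the border
    near_outside = ndimage.binary_dilation(outside, structure=_STRUCT[4])
    exposed = np.zeros(n + 1, dtype=bool)
    exposed[np.unique(label_image[near_outside])] = True
    exposed[np.unique(label_image[0, :])] = True
    exposed[np.unique(label_image[-1, :])] = True
    exposed[np.unique(label_image[:, 0])] = True
    exposed[np.unique(label_image[:, -1])] = True
    return ~exposed[1:]


def detect_nucleoli(frame: GrayFrame, config: PipelineConfig | None = None) -> PointSet:
    """Extract nucleolus centroids from one phase-contrast frame.

    Returns the integer-rounded centroids of dark size-filtered regions that
    (a) contain their own rounded centroid pixel and (b) are enclosed by a
    second dark region (the nuclear ring).  An image with no detections
    yields an empty point set.
    """
    cfg = config or PipelineConfig()
    mask = adaptive_binarize(frame, cfg.binarize_window, cfg.binarize_offset,
                             polarity="dark", method=cfg.binarize_method)
    regions = label_components(mask, cfg.connectivity)
    cand = filter_by_size(regions, cfg.nucleolus_min_px, cfg.nucleolus_max_px)
    if cand.n_regions == 0:
        return PointSet(np.zeros((0, 2), int), "nucleolus", frame.shape)

    enclosed = enclosed_labels(mask, cand.label_image)

    pts = []
    cent = _round_half_down(cand.centroids)
    for k in range(cand.n_regions):
        r, c = cent[k]
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            continue
        if cand.label_image[r, c] != k + 1:      # centroid outside its region
            continue
        if not enclosed[k]:                       # no surrounding nuclear ring
            continue
        pts.append((r, c))
    pts_arr = np.array(sorted(pts), dtype=int).reshape(-1, 2)
    return PointSet(pts_arr, "nucleolus", frame.shape)
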