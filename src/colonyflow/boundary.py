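"""Cell-boundary branch points — procedure (2) of the pipeline.

Inside a keratinocyte colony the cell-cell boundaries show as a bright mesh
in phase contrast.  The mesh is extracted by adaptive binarization (bright
polarity), cleaned by morphological opening and closing, stripped of small
regions (<= 250 px), thinned to a 1-px skeleton by the Zhang-Suen algorithm,
and its bifurcations are located with the Crossing Number (CN) method:

    CN = 0.5 * sum_{i=1..8} |P_i - P_{i+1}|,   P_9 = P_1

over the 8-neighborhood traversed in fixed cyclic order.  A skeleton pixel
with CN == 3 is a branch point; since feeder cells form no mesh, branch
points are dense exactly inside colonies.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import GrayFrame, PipelineConfig, PointSet
from .nucleoli import adaptive_binarize, label_components, _STRUCT

__all__ = [
    "extract_boundary_mask",
    "zhang_suen_thin",
    "crossing_number",
    "detect_branch_points",
]

# 8-neighbor offsets in fixed cyclic order: clockwise from the top-left.
CN_NEIGHBOR_ORDER: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def extract_boundary_mask(frame: GrayFrame, config: PipelineConfig | None = None
                          ) -> np.ndarray:
    """Bright cell-cell boundary mesh as a cleaned binary mask."""
    cfg = config or PipelineConfig()
    mask = adaptive_binarize(frame, cfg.binarize_window, cfg.binarize_offset,
                             polarity="bright", method=cfg.binarize_method)
    se = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_opening(mask, structure=se)
    mask = ndimage.binary_closing(mask, structure=se)
    # drop regions of boundary_min_region_px pixels or fewer
    lab, n = ndimage.label(mask, structure=_STRUCT[cfg.connectivity])
    if n:
        areas = np.bincount(lab.ravel(), minlength=n + 1)
        small = areas <= cfg.boundary_min_region_px
        small[0] = False
        mask[small[lab]] = False
    return mask


def _neighbor_views(padded: np.ndarray) -> list[np.ndarray]:
    """The 8 neighbor planes of a 1-px-padded image, in CN cyclic order."""
    views = []
    for dr, dc in CN_NEIGHBOR_ORDER:
        views.append(padded[1 + dr: padded.shape[0] - 1 + dr,
                            1 + dc: padded.shape[1] - 1 + dc])
    return views


def _zhang_suen_pass(img: np.ndarray) -> np.ndarray:
    """Run Zhang-Suen two-subiteration thinning to a fixed point."""
    img = img.astype(np.uint8)
    while True:
        changed = False
        for step in (0, 1):
            p = np.pad(img, 1)
            # classic notation: P2=N, P3=NE, P4=E, P5=SE, P6=S, P7=SW, P8=W, P9=NW
            P2 = p[:-2, 1:-1]; P3 = p[:-2, 2:]; P4 = p[1:-1, 2:]
            P5 = p[2:, 2:];    P6 = p[2:, 1:-1]; P7 = p[2:, :-2]
            P8 = p[1:-1, :-2]; P9 = p[:-2, :-2]
            seq = (P2, P3, P4, P5, P6, P7, P8, P9, P2)
            B = P2 + P3 + P4 + P5 + P6 + P7 + P8 + P9
            A = np.zeros_like(B)
            for i in range(8):
                A += (seq[i] == 0) & (seq[i + 1] == 1)
            if step == 0:
                cond = (P2 * P4 * P6 == 0) & (P4 * P6 * P8 == 0)
            else:
                cond = (P2 * P4 * P8 == 0) & (P2 * P6 * P8 == 0)
            delete = (img == 1) & (B >= 2) & (B <= 6) & (A == 1) & cond
            if delete.any():
                img[delete] = 0
                changed = True
        if not changed:
            return img


def _is_simple(img: np.ndarray, r: int, c: int) -> bool:
    """Topology-preserving (simple) point test for 8-connected foreground.

    Removal of a simple pixel changes neither the number of foreground
    8-components nor of background 4-components: its punctured 3x3
    neighborhood must hold exactly one foreground 8-component and exactly
    one background 4-component that is 4-adjacent to the pixel.
    """
    r0, r1 = max(r - 1, 0), min(r + 2, img.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, img.shape[1])
    win = np.zeros((3, 3), dtype=bool)
    win[r0 - (r - 1): 3 - ((r + 2) - r1), c0 - (c - 1): 3 - ((c + 2) - c1)] = \
        img[r0:r1, c0:c1] > 0
    win[1, 1] = False
    if not win.any():
        return False                      # isolated pixel
    _, n_fg = ndimage.label(win, structure=_STRUCT[8])
    if n_fg != 1:
        return False
    bg = ~win
    bg[1, 1] = False
    bg_lab, _ = ndimage.label(bg, structure=_STRUCT[4])
    adj = {bg_lab[0, 1], bg_lab[1, 0], bg_lab[1, 2], bg_lab[2, 1]} - {0}
    return len(adj) == 1


def _prune_staircases(img: np.ndarray) -> np.ndarray:
    """Remove residual 2x2 foreground blocks left by Zhang-Suen thinning.

    Within each block the first pixel (raster order of block, then TL, TR,
    BL, BR) whose removal is topology-preserving is deleted; repeated until
    no 2x2 block remains.
    """
    img = img.astype(np.uint8).copy()
    for _ in range(img.size):  # safety bound; converges in a few passes
        blocks = (img[:-1, :-1] & img[1:, :-1] & img[:-1, 1:] & img[1:, 1:])
        coords = np.argwhere(blocks)
        if coords.size == 0:
            break
        removed_any = False
        for rr, cc in coords:
            if not (img[rr, cc] and img[rr + 1, cc] and img[rr, cc + 1]
                    and img[rr + 1, cc + 1]):
                continue  # block already broken by an earlier removal
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                pr, pc = rr + dr, cc + dc
                if _is_simple(img, pr, pc):
                    img[pr, pc] = 0
                    removed_any = True
                    break
        if not removed_any:
            break
    return img


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px skeleton (Zhang-Suen + staircase pruning).

    The two-subiteration thinning runs to a fixed point; a final pruning
    pass removes the algorithm's known residual 2x2 blocks so that the
    Crossing Number of junction pixels is well defined.
    """
    img = _zhang_suen_pass(np.asarray(mask, dtype=bool))
    img = _prune_staircases(img)
    return img.astype(bool)


def crossing_number(skeleton: np.ndarray, pixel: tuple[int, int]) -> int:
    """CN of one skeleton pixel; border pixels are evaluated with 0-padding.

    Raises ``ValueError`` for a background pixel (CN is defined on the
    skeleton only).
    """
    skel = np.asarray(skeleton, dtype=bool)
    r, c = pixel
    if not skel[r, c]:
        raise ValueError(f"pixel {pixel} is not on the skeleton")
    p = np.pad(skel.astype(np.uint8), 1)
    vals = [int(p[1 + r + dr, 1 + c + dc]) for dr, dc in CN_NEIGHBOR_ORDER]
    vals.append(vals[0])  # P_9 = P_1
    return int(sum(abs(vals[i] - vals[i + 1]) for i in range(8)) // 2)


def crossing_number_map(skeleton: np.ndarray) -> np.ndarray:
    """CN evaluated at every pixel (valid where the skeleton is True)."""
    skel = np.asarray(skeleton, dtype=bool)
    p = np.pad(skel.astype(np.int16), 1)
    nbrs = _neighbor_views(p)
    nbrs.append(nbrs[0])
    total = np.zeros(skel.shape, dtype=np.int16)
    for i in range(8):
        total += np.abs(nbrs[i] - nbrs[i + 1])
    return (total // 2).astype(int)


def detect_branch_points(skeleton: np.ndarray,
                         config: PipelineConfig | None = None) -> PointSet:
    """All skeleton pixels with CN == 3 (optionally also CN == 4).

    By default only CN == 3 bifurcations count; 4-way crossings can be
    included via ``config.include_crossings``.
    """
    cfg = config or PipelineConfig()
    skel = np.asarray(skeleton, dtype=bool)
    cn = crossing_number_map(skel)
    hit = skel & (cn == 3)
    if cfg.include_crossings:
        hit |= skel & (cn == 4)
    pts = np.argwhere(hit)
    return PointSet(pts, "branch_point", skel.shape)
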