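"""Image, point-set and configuration I/O.

Time series may arrive either as a multi-page TIFF stack or as a list of
numbered single-image files (TIFF/PNG); both are common microscope exports.
Multi-channel inputs are collapsed to grayscale by the channel (luminance)
average.  Intensities are normalized to float ``[0, 1]`` on read and written
back as 8-bit at the boundary.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import GrayFrame, PipelineConfig, PointSet

__all__ = [
    "read_frames",
    "write_frames",
    "write_mask",
    "read_mask",
    "write_points",
    "read_points",
    "load_config",
    "save_config",
    "write_run_metadata",
]

PathLike = Union[str, os.PathLike]


def _to_float01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:  # multi-channel -> luminance average
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() > 1.0:
        # integer-coded intensities stored in a float container, or plain ints
        arr = arr / (255.0 if arr.max() <= 255 else 65535.0)
    return np.clip(arr, 0.0, 1.0)


def _read_single(path: Path) -> list[np.ndarray]:
    """Read one file; a multi-page TIFF yields one array per page."""
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(str(path))
            if data.ndim == 3 and data.shape[-1] not in (3, 4):
                return [np.asarray(p) for p in data]     # page stack
            return [np.asarray(data)]
        return [np.asarray(iio.imread(path))]
    except Exception as exc:   # plugin backends raise heterogeneous errors
        raise OSError(f"cannot read image file {path}: {exc}") from exc


def read_frames(
    path_or_list: Union[PathLike, Sequence[PathLike]],
    interval_min: float = 5.0,
    pixel_size_um: float | None = None,
) -> list[GrayFrame]:
    """Read an ordered grayscale time series.

    ``path_or_list`` may be one multi-page TIFF, one single image, a
    directory of numbered frames, or an explicit list of files (kept in the
    given order; a directory is sorted by name).
    """
    if isinstance(path_or_list, (str, os.PathLike)):
        p = Path(path_or_list)
        if p.is_dir():
            files = sorted(
                q for q in p.iterdir()
                if q.suffix.lower() in (".png", ".tif", ".tiff")
            )
            if not files:
                raise OSError(f"no image files found in directory {p}")
        else:
            files = [p]
    else:
        files = [Path(q) for q in path_or_list]

    arrays: list[np.ndarray] = []
    for f in files:
        arrays.extend(_read_single(f))
    if not arrays:
        raise OSError("no frames decoded")

    frames = [_to_float01(a) for a in arrays]
    if len({f.shape for f in frames}) > 1:
        raise ValueError(
            f"frames have mixed shapes: {sorted({f.shape for f in frames})}"
        )
    return [
        GrayFrame(pixels=a, frame_index=i, interval_min=interval_min,
                  pixel_size_um=pixel_size_um)
        for i, a in enumerate(frames)
    ]


def write_frames(frames: Iterable[GrayFrame], out_dir: PathLike,
                 prefix: str = "frame") -> list[Path]:
    """Write frames as numbered 8-bit PNGs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in frames:
        p = out / f"{prefix}_{fr.frame_index:04d}.png"
        iio.imwrite(p, (np.clip(fr.pixels, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths


def write_mask(mask: np.ndarray, path: PathLike) -> None:
    """Save a boolean mask as an 8-bit 0/255 image (PNG or TIFF by suffix)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    try:
        iio.imwrite(Path(path), arr)
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path: PathLike) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; any nonzero pixel is True."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def write_points(points: PointSet, path: PathLike) -> None:
    """Save a point set as CSV with header ``row,col,kind``."""
    df = pd.DataFrame(
        {"row": points.points[:, 0], "col": points.points[:, 1],
         "kind": points.kind}
    )
    try:
        df.to_csv(Path(path), index=False)
    except OSError as exc:
        raise OSError(f"cannot write points to {path}: {exc}") from exc


def read_points(path: PathLike) -> PointSet:
    df = pd.read_csv(Path(path))
    pts = df[["row", "col"]].to_numpy(dtype=int)
    kinds = df["kind"].unique().tolist() if len(df) else ["pooled"]
    kind = kinds[0] if len(kinds) == 1 else "pooled"
    return PointSet(points=pts, kind=kind)


def load_config(path: PathLike) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML (or JSON) mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_run_metadata(path: PathLike, config: PipelineConfig, seed: int,
                       extra: dict | None = None) -> None:
    """Write the JSON run-metadata record accompanying every output set."""
    from . import __version__

    record = {
        "software": "colonyflow",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
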