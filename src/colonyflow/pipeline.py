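"""End-to-end orchestration: extract -> flow -> speed -> stats.

``run_pipeline`` processes one time series (one colony field) and writes
masks, landmark CSVs, per-pair speeds and a reproducible run manifest.
``run_screen`` processes several conditions with >= 3 colonies each and
produces the screening statistics (Mann-Whitney for two conditions,
Kruskal-Wallis + Dunn vs control for more).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .colony import extract_colony_frame
from .io import PathLike, read_frames, write_mask, write_points, write_run_metadata
from .model import ColonyMask, GrayFrame, PipelineConfig
from .motion import speed_timecourse
from .stats import compare_multi_groups, compare_two_groups

__all__ = ["RunManifest", "run_pipeline", "run_screen"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output set."""

    config: dict
    inputs: list[dict]                    # path + sha256 per input file
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    seed: int = 0
    timings_s: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_series(src: Union[PathLike, Sequence[GrayFrame]],
                 config: PipelineConfig) -> tuple[list[GrayFrame], list[dict]]:
    if isinstance(src, (list, tuple)) and src and isinstance(src[0], GrayFrame):
        return list(src), []
    frames = read_frames(src, config.interval_min, config.pixel_size_um)
    p = Path(src)
    files = sorted(q for q in p.iterdir()
                   if q.suffix.lower() in (".png", ".tif", ".tiff")) \
        if p.is_dir() else [p]
    return frames, [{"path": str(f), "sha256": _sha256(f)} for f in files]


def run_pipeline(frames_src: Union[PathLike, Sequence[GrayFrame]],
                 config: PipelineConfig | None = None,
                 out_dir: PathLike = "colonyflow_out",
                 extraction_only: bool = False,
                 colony_id: str = "colony") -> RunManifest:
    """Full workflow on one time series; returns the run manifest.

    With a single frame (or ``extraction_only``) the speed stage is skipped
    with a notice.  A series in which every frame yields an empty colony
    mask ends with a dataset-level diagnostic in the manifest rather than a
    crash.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), inputs=[], seed=cfg.random_seed)

    t0 = time.perf_counter()
    frames, inputs = _load_series(frames_src, cfg)
    manifest.inputs = inputs
    manifest.timings_s["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    masks: list[ColonyMask] = []
    rows = []
    for fr in frames:
        mask, nucleoli, branches = extract_colony_frame(fr, cfg)
        masks.append(mask)
        mp = out / f"mask_{fr.frame_index:04d}.png"
        write_mask(mask.pixels, mp)
        np_path = out / f"nucleoli_{fr.frame_index:04d}.csv"
        bp_path = out / f"branch_points_{fr.frame_index:04d}.csv"
        write_points(nucleoli, np_path)
        write_points(branches, bp_path)
        manifest.outputs += [str(mp), str(np_path), str(bp_path)]
        rows.append({"frame_index": fr.frame_index,
                     "n_nucleoli": len(nucleoli),
                     "n_branch_points": len(branches),
                     "colony_area_px": mask.area_px})
    frame_csv = out / "frames.csv"
    pd.DataFrame(rows).to_csv(frame_csv, index=False)
    manifest.outputs.append(str(frame_csv))
    manifest.timings_s["extract"] = time.perf_counter() - t0

    if all(m.is_empty for m in masks):
        manifest.warnings.append(
            "no valid colony mask in any frame: check that the input shows a "
            "colony and that thresholds suit the acquisition")
    elif len(frames) >= 2 and not extraction_only:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            summary = speed_timecourse(frames, masks, cfg, colony_id=colony_id)
        manifest.warnings += [str(w.message) for w in wlist]
        speed_csv = out / "speeds.csv"
        pd.DataFrame({
            "colony_id": colony_id,
            "frame_pair": [f"{t}-{t + 1}" for t in range(len(frames) - 1)
                           if (t, t + 1) not in summary.skipped_pairs],
            "mean_speed": summary.per_pair_means,
            "unit": summary.unit,
        }).to_csv(speed_csv, index=False)
        summary_json = out / "speed_summary.json"
        with open(summary_json, "w") as fh:
            json.dump({"colony_id": colony_id, "mean_speed": summary.mean_speed,
                       "sd_speed": summary.sd_speed, "unit": summary.unit,
                       "per_pair_means": summary.per_pair_means,
                       "n_pixels": summary.n_pixels}, fh, indent=2)
        manifest.outputs += [str(speed_csv), str(summary_json)]
        manifest.timings_s["flow"] = time.perf_counter() - t0
    else:
        log.info("speed stage skipped (%s)",
                 "extraction-only" if extraction_only else "single frame")

    write_run_metadata(out / "run_metadata.json", cfg, cfg.random_seed)
    manifest.outputs.append(str(out / "run_metadata.json"))
    manifest.write(out / "manifest.json")
    return manifest


def run_screen(conditions: Mapping[str, Sequence[Union[PathLike,
                                                       Sequence[GrayFrame]]]],
               config: PipelineConfig | None = None,
               control_label: str | None = None,
               out_dir: PathLike | None = None) -> dict:
    """Multi-condition screening readout on per-colony mean speeds.

    ``conditions`` maps a condition label to its list of colony time series
    (paths or in-memory frame lists, >= 3 colonies each, >= 2 frames per
    colony; 2-3 frames at 5-minute intervals suffice).  Returns a report
    dict with the per-colony speeds, the test and p-value(s); optionally
    writes a violin-ready long-format CSV plus a stats JSON.
    """
    cfg = config or PipelineConfig()
    if len(conditions) < 2:
        raise ValueError("screening needs at least two conditions")
    control_label = control_label or next(iter(conditions))

    speeds: dict[str, list[float]] = {}
    long_rows = []
    for label, series_list in conditions.items():
        speeds[label] = []
        for i, src in enumerate(series_list):
            frames, _ = _load_series(src, cfg)
            if len(frames) < 2:
                log.warning("condition %s colony %d: <2 frames, excluded",
                            label, i)
                continue
            masks = [extract_colony_frame(fr, cfg)[0] for fr in frames]
            try:
                summary = speed_timecourse(frames, masks, cfg,
                                           colony_id=f"{label}-{i}",
                                           condition_label=label)
            except ValueError as exc:
                log.warning("condition %s colony %d excluded: %s", label, i, exc)
                continue
            speeds[label].append(summary.mean_speed)
            for t, sp in zip(
                    [p for p in range(len(frames) - 1)
                     if (p, p + 1) not in summary.skipped_pairs],
                    summary.per_pair_means):
                long_rows.append({"condition": label, "colony_id": f"{label}-{i}",
                                  "frame_pair": f"{t}-{t + 1}",
                                  "mean_speed": sp, "unit": summary.unit})

    usable = {k: v for k, v in speeds.items() if len(v) >= 3}
    if len(usable) < 2:
        raise ValueError("fewer than two conditions with >= 3 usable colonies")
    if len(usable) == 2:
        labels = list(usable)
        if control_label in labels:        # control first for sign convention
            labels = [control_label] + [l for l in labels if l != control_label]
        result = compare_two_groups(usable[labels[0]], usable[labels[1]],
                                    labels=(labels[0], labels[1]))
    else:
        result = compare_multi_groups(usable, control=control_label)

    report = {
        "per_colony_speeds": speeds,
        "control": control_label,
        "comparison": result.to_dict(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(long_rows).to_csv(out / "screen_speeds_long.csv", index=False)
        with open(out / "screen_stats.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        write_run_metadata(out / "run_metadata.json", cfg, cfg.random_seed)
    return report
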