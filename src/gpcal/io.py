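"""Readers and writers for the pipeline's on-disk formats.

Movies are multi-frame TIFF (16-bit on write); ROI sets are an integer
label-mask TIFF plus a metadata CSV; traces are tidy CSV (one row per frame
per ROI); stimulus protocols are CSV (time_s, epoch); run manifests and
ground-truth sidecars are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import RecordingMovie, RoiSet, Stimulus, Trace

TRACE_COLUMNS = ["roi_id", "frame", "time_s", "F"]
STIMULUS_COLUMNS = ["time_s", "epoch"]
ROI_COLUMNS = ["roi_id", "class", "centroid_y", "centroid_x", "n_pixels"]

FLOAT_FORMAT = "%.9g"  # fixed formatting keeps reruns bit-identical


def write_movie(path: str | Path, movie: RecordingMovie) -> None:
    """Write a movie as 16-bit multi-frame TIFF (values clipped to uint16)."""
    frames = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), frames, metadata={"frame_rate_hz": movie.frame_rate})


def read_movie(
    path: str | Path, frame_rate: float, stimuli: list[Stimulus] | None = None
) -> RecordingMovie:
    frames = tifffile.imread(str(path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return RecordingMovie(frames=frames, frame_rate=frame_rate, stimuli=stimuli or [])


def write_roi_set(mask_path: str | Path, meta_path: str | Path, rois: RoiSet) -> None:
    tifffile.imwrite(str(mask_path), rois.label_mask.astype(np.uint16))
    rois.metadata().to_csv(meta_path, index=False, float_format=FLOAT_FORMAT)


def read_roi_set(mask_path: str | Path, meta_path: str | Path | None = None) -> RoiSet:
    mask = tifffile.imread(str(mask_path)).astype(int)
    classes: dict[int, str] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        classes = {int(r.roi_id): str(r["class"]) for _, r in meta.iterrows()}
    return RoiSet(label_mask=mask, classes=classes)


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "roi_id": tr.roi_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.times_s,
                    "F": tr.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def write_traces(path: str | Path, traces: list[Trace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_traces(path: str | Path, frame_rate: float | None = None) -> list[Trace]:
    """Read tidy trace CSV; the frame rate is inferred from time_s if not given."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path}: missing columns {sorted(missing)}")
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("frame")
        if frame_rate is None:
            dt = np.diff(sub["time_s"].to_numpy())
            if dt.size == 0 or not np.allclose(dt, dt[0]):
                raise ValueError(f"trace CSV {path}: cannot infer a fixed frame rate")
            fr = 1.0 / float(dt[0])
        else:
            fr = frame_rate
        traces.append(Trace(roi_id=int(roi_id), values=sub["F"].to_numpy(), frame_rate=fr))
    return traces


def write_stimuli(path: str | Path, stimuli: list[Stimulus]) -> None:
    pd.DataFrame(
        {"time_s": [s.time_s for s in stimuli], "epoch": [s.epoch for s in stimuli]}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_stimuli(path: str | Path) -> list[Stimulus]:
    df = pd.read_csv(path)
    missing = set(STIMULUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stimulus CSV {path}: missing columns {sorted(missing)}")
    return [Stimulus(time_s=float(r.time_s), epoch=str(r.epoch)) for r in df.itertuples()]


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
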