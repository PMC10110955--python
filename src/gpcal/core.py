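"""Core data containers shared across the pipeline.

A recording is a 3D fluorescence stack (time x height x width) at a fixed
frame rate, together with the stimulus protocol (stimulus times and the drug
epoch each stimulus belongs to). Somatic regions of interest are supplied as
an integer label mask; per-ROI mean-intensity time series are the working
representation for all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPOCHS = ("baseline", "antagonist", "washout")


@dataclass
class Stimulus:
    """One stimulus delivery: time in seconds and the drug epoch it falls in."""

    time_s: float
    epoch: str = "baseline"

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}; expected one of {EPOCHS}")


@dataclass
class RecordingMovie:
    """Time-lapse fluorescence stack with acquisition metadata.

    Frame ``i`` is acquired at time ``i / frame_rate`` (frame 0 at t=0).
    Intensities are arbitrary fluorescence units.
    """

    frames: np.ndarray  # (T, H, W)
    frame_rate: float  # Hz
    stimuli: list[Stimulus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (time, height, width) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        times = [s.time_s for s in self.stimuli]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("stimulus times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration_s):
            raise ValueError("stimulus times must fall within the recording")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class RoiSet:
    """Integer label mask (0 = background) plus per-ROI class annotations."""

    label_mask: np.ndarray  # (H, W) int
    classes: dict[int, str] = field(default_factory=dict)  # roi_id -> neuron|glia

    def __post_init__(self) -> None:
        self.label_mask = np.asarray(self.label_mask)
        if self.label_mask.ndim != 2:
            raise ValueError("label mask must be 2D")
        if np.any(self.label_mask < 0):
            raise ValueError("labels must be non-negative")
        for roi_id, cls in self.classes.items():
            if cls not in ("neuron", "glia"):
                raise ValueError(f"ROI {roi_id}: class must be 'neuron' or 'glia'")

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.label_mask)
        return [int(i) for i in ids if i > 0]

    def roi_class(self, roi_id: int) -> str:
        return self.classes.get(roi_id, "neuron")

    def metadata(self) -> pd.DataFrame:
        """Tidy per-ROI table: id, class, centroid, pixel count."""
        rows = []
        for roi_id in self.roi_ids:
            ys, xs = np.nonzero(self.label_mask == roi_id)
            rows.append(
                {
                    "roi_id": roi_id,
                    "class": self.roi_class(roi_id),
                    "centroid_y": float(ys.mean()),
                    "centroid_x": float(xs.mean()),
                    "n_pixels": int(ys.size),
                }
            )
        return pd.DataFrame(rows, columns=["roi_id", "class", "centroid_y", "centroid_x", "n_pixels"])


@dataclass
class Trace:
    """Per-ROI mean fluorescence time series at a fixed frame rate."""

    roi_id: int
    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1D")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate
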