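"""Movie preprocessing: rigid motion correction and ROI trace extraction."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .core import RecordingMovie, RoiSet, Trace
from .synthetic import shift_frame_int

log = logging.getLogger(__name__)

__all__ = ["motion_correct", "extract_traces", "reference_frame"]


def reference_frame(movie: RecordingMovie, n_frames: int = 10) -> np.ndarray:
    """Registration reference: mean of the first ``n_frames`` frames."""
    return movie.frames[: min(n_frames, movie.n_frames)].mean(axis=0)


def motion_correct(
    movie: RecordingMovie,
    reference: int | np.ndarray | None = None,
    max_shift: int | None = None,
    subpixel: bool = False,
) -> tuple[RecordingMovie, pd.DataFrame]:
    """Rigidly register every frame to a reference by cross-correlation.

    The reported (dy, dx) for frame ``i`` is the translation *applied to that
    frame* to align it with the reference (so a frame whose content drifted
    by +d is reported with shift -d). Shifts are integer pixels by default
    (``subpixel=True`` refines the estimate but frames are still moved by the
    rounded shift); exposed borders are filled with the edge value.

    Returns the corrected movie and a per-frame shift table with the
    valid-pixel fraction untouched by edge fill.
    """
    if movie.n_frames < 2:
        raise ValueError("motion correction needs at least 2 frames")
    if reference is None:
        ref = reference_frame(movie)
    elif isinstance(reference, (int, np.integer)):
        ref = movie.frames[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)

    if np.ptp(movie.frames) == 0:
        log.warning("all-constant movie: motion correction returns zero shifts")
        table = pd.DataFrame(
            {"frame": np.arange(movie.n_frames), "dy": 0.0, "dx": 0.0, "valid_fraction": 1.0}
        )
        return replace(movie, frames=movie.frames.copy()), table

    h, w = ref.shape
    corrected = np.empty_like(movie.frames)
    rows = []
    for i, frame in enumerate(movie.frames):
        shift, _, _ = phase_cross_correlation(
            ref, frame, normalization=None,
            upsample_factor=10 if subpixel else 1,
        )
        dy, dx = float(shift[0]), float(shift[1])
        if max_shift is not None:
            dy = float(np.clip(dy, -max_shift, max_shift))
            dx = float(np.clip(dx, -max_shift, max_shift))
        iy, ix = int(round(dy)), int(round(dx))
        corrected[i] = shift_frame_int(frame, iy, ix)
        valid = (h - abs(iy)) * (w - abs(ix)) / (h * w)
        rows.append({"frame": i, "dy": dy, "dx": dx, "valid_fraction": valid})
    table = pd.DataFrame(rows)
    return replace(movie, frames=corrected), table


def extract_traces(
    movie: RecordingMovie, rois: RoiSet, roi_ids: list[int] | None = None
) -> list[Trace]:
    """Average each ROI's pixels per frame into a soma intensity profile.

    ``roi_ids`` restricts (and orders) the extraction; requesting a label
    that does not occur in the mask is an error naming the label.
    """
    if rois.label_mask.shape != movie.frames.shape[1:]:
        raise ValueError("label mask shape must match the frame shape")
    if roi_ids is None:
        roi_ids = rois.roi_ids
    flat_mask = rois.label_mask.ravel()
    flat_movie = movie.frames.reshape(movie.n_frames, -1)
    traces = []
    for roi_id in roi_ids:
        sel = flat_mask == roi_id
        if not sel.any():
            raise ValueError(f"ROI label {roi_id} absent from the mask")
        traces.append(
            Trace(
                roi_id=roi_id,
                values=flat_movie[:, sel].mean(axis=1),
                frame_rate=movie.frame_rate,
            )
        )
    return traces
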