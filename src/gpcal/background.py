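"""Two-step background subtraction and dF/F0 normalization.

Photobleaching puts a slow monotone decay under every ROI trace. The
correction removes it without flattening the calcium transients:

1. a centered 200-frame moving average is subtracted from the raw trace,
   leaving a residual in which transients stand out against a near-zero
   background;
2. frames whose residual exceeds ``threshold_k`` times the background noise
   SD seed signal regions, each grown outward until the residual falls back
   below a re-entry level — this 1D mask marks frames contaminated by signal;
3. a cubic spline fit through the *unmasked* raw samples (least squares with
   sparse knots by default, interpolating on request), bridging the masked
   spans, is the background (bleaching) trace F0(t);
4. the corrected trace is dF/F0 = (F - F0) / F0, with the time-varying F0 as
   denominator so that event amplitudes are bleach-invariant.

The noise SD is estimated robustly (1.4826 x MAD) by default, because a raw
SD of the residual is inflated by the very transients being detected; a
plain-SD mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Trace

log = logging.getLogger(__name__)

__all__ = ["moving_average", "detect_signal_mask", "fit_background", "correct", "BackgroundFit"]


def moving_average(values: np.ndarray, window_frames: int = 200) -> np.ndarray:
    """Centered running mean with a symmetrically shrinking window at the edges.

    Frame ``i`` averages frames ``i - h .. i + h`` with
    ``h = min((w - 1) // 2, i, n - 1 - i)``: the full half-width in the
    interior, shrinking symmetrically toward the trace ends. Keeping the
    window symmetric makes the running mean exact on linear trends at *every*
    frame, so a sloped (bleaching) baseline leaves no spurious residual at
    the edges; an asymmetrically truncated window would be biased there by
    roughly slope x half-window. Even windows are shrunk to the nearest odd
    symmetric span. A window longer than the trace truncates everywhere
    (logged).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a non-empty 1D trace")
    w = int(window_frames)
    if w < 1:
        raise ValueError("window_frames must be >= 1")
    if w > x.size:
        log.warning("moving-average window (%d) longer than trace (%d); truncating", w, x.size)
    n = x.size
    idx = np.arange(n)
    h = np.minimum((w - 1) // 2, np.minimum(idx, n - 1 - idx))
    lo = idx - h
    hi = idx + h
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def robust_sd(values: np.ndarray) -> float:
    """Gaussian-consistent robust scale: 1.4826 x median absolute deviation."""
    x = np.asarray(values, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_signal_mask(
    residual: np.ndarray,
    threshold_k: float = 3.0,
    reentry_fraction: float = 0.5,
    sd_estimator: str = "mad",
) -> tuple[np.ndarray, float]:
    """Flag frames carrying fluorescence signal above the residual noise.

    Frames with residual > ``threshold_k`` x SD seed signal regions; each
    region extends in both directions until the residual first drops below
    ``reentry_fraction`` x SD, so that event shoulders do not anchor the
    background spline. Returns the boolean mask and the SD estimate.
    """
    r = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residual must be finite")
    if sd_estimator == "mad":
        sd = robust_sd(r)
    elif sd_estimator == "sd":
        sd = float(np.std(r))
    else:
        raise ValueError("sd_estimator must be 'mad' or 'sd'")

    if sd == 0.0:
        mask = r != 0.0
        if mask.any():
            log.warning("zero-variance residual: every nonzero sample treated as signal")
        return mask, sd

    seeds = r > threshold_k * sd
    if not seeds.any():
        return np.zeros_like(seeds), sd
    above = r > reentry_fraction * sd
    # connected runs of `above`; keep the runs that contain at least one seed
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    mask = np.zeros_like(above)
    for s, e in zip(starts, ends):
        if seeds[s:e].any():
            mask[s:e] = True
    return mask, sd


def fit_background(
    values: np.ndarray,
    signal_mask: np.ndarray,
    mode: str = "lsq",
    knot_spacing_frames: int = 50,
) -> np.ndarray:
    """Cubic-spline background through the unmasked samples, at every frame.

    ``mode="lsq"`` (default) fits a least-squares cubic spline with interior
    knots every ``knot_spacing_frames`` to the unmasked samples. Photobleaching
    varies on tens-of-seconds time scales, so sparse knots track it exactly
    while averaging the per-frame noise within each knot interval; masked
    spans are bridged stably by the neighbouring segments. ``mode="interpolate"``
    passes exactly through every unmasked sample (the fully literal variant;
    with noisy anchors it propagates noise into masked spans and is kept for
    strict reproduction and noise-free data). Beyond the first/last unmasked
    frame the boundary value is held rather than extrapolating the cubic.
    """
    x = np.asarray(values, dtype=float)
    mask = np.asarray(signal_mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("signal_mask must match the trace shape")
    anchors = np.flatnonzero(~mask)
    if anchors.size < 4:
        raise ValueError(
            f"only {anchors.size} background frames; a cubic fit needs >= 4 "
            "(relax threshold_k or shorten the mask extension)"
        )
    idx = np.arange(x.size, dtype=float)
    clipped = np.clip(idx, anchors[0], anchors[-1])
    if mode == "interpolate":
        spline = CubicSpline(anchors, x[anchors])
        return np.asarray(spline(clipped), dtype=float)
    if mode != "lsq":
        raise ValueError("mode must be 'lsq' or 'interpolate'")

    from scipy.interpolate import LSQUnivariateSpline

    xa = anchors.astype(float)
    ya = x[anchors]
    # interior knots on a regular grid, keeping only those with >= 4 anchors
    # between neighbours (Schoenberg-Whitney) so masked spans drop their knots
    knots = np.arange(xa[0] + knot_spacing_frames, xa[-1] - knot_spacing_frames / 2,
                      knot_spacing_frames, dtype=float)
    if knots.size:
        counts = np.histogram(xa, bins=np.concatenate(([xa[0]], knots, [xa[-1]])))[0]
        keep = []
        since_last = counts[0]
        for i, knot in enumerate(knots):
            if since_last >= 4 and counts[i + 1 :].sum() >= 4:
                keep.append(knot)
                since_last = counts[i + 1]
            else:
                since_last += counts[i + 1]
        knots = np.asarray(keep)
    if knots.size == 0:
        # too few anchors for interior knots: single least-squares cubic
        coeffs = np.polyfit(xa, ya, min(3, anchors.size - 1))
        return np.asarray(np.polyval(coeffs, clipped), dtype=float)
    spline = LSQUnivariateSpline(xa, ya, t=knots, k=3)
    return np.asarray(spline(clipped), dtype=float)


@dataclass
class BackgroundFit:
    """Audit record of one trace's background subtraction."""

    roi_id: int
    raw: np.ndarray
    moving_avg: np.ndarray
    residual: np.ndarray
    signal_mask: np.ndarray
    background: np.ndarray
    corrected: Trace  # dF/F0
    noise_sd: float  # SD estimate of the moving-average residual
    window_frames: int
    threshold_k: float

    @property
    def mask_fraction(self) -> float:
        return float(self.signal_mask.mean())


def correct(
    trace: Trace,
    window_frames: int = 200,
    threshold_k: float = 3.0,
    reentry_fraction: float = 0.5,
    sd_estimator: str = "mad",
    background_mode: str = "lsq",
    knot_spacing_frames: int = 50,
    second_pass: bool = False,
) -> BackgroundFit:
    """Full two-step correction of one trace to dF/F0.

    Runs moving average -> signal mask -> spline background, then normalizes
    ``(raw - background) / background``. With ``second_pass=True`` the mask is
    re-derived from the residual against the fitted background and the spline
    refit once (off by default; the standard procedure is single-pass).
    Deterministic: identical input and parameters give identical output.
    """
    raw = trace.values
    ma = moving_average(raw, window_frames)
    residual = raw - ma
    mask, sd = detect_signal_mask(residual, threshold_k, reentry_fraction, sd_estimator)
    bg = fit_background(raw, mask, mode=background_mode, knot_spacing_frames=knot_spacing_frames)
    if second_pass:
        mask2, sd2 = detect_signal_mask(raw - bg, threshold_k, reentry_fraction, sd_estimator)
        mask = mask | mask2
        bg = fit_background(raw, mask, mode=background_mode, knot_spacing_frames=knot_spacing_frames)
        sd = sd2
    if np.any(bg <= 0):
        raise ValueError("fitted background is non-positive; non-physical fluorescence")
    corrected = Trace(roi_id=trace.roi_id, values=(raw - bg) / bg, frame_rate=trace.frame_rate)
    return BackgroundFit(
        roi_id=trace.roi_id,
        raw=raw,
        moving_avg=ma,
        residual=residual,
        signal_mask=mask,
        background=bg,
        corrected=corrected,
        noise_sd=sd,
        window_frames=window_frames,
        threshold_k=threshold_k,
    )
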