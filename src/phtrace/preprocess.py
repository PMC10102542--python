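"""Background subtraction, moving-average smoothing, and dF/F0 normalization.

Bleaching is deliberately *not* modelled or regressed out: the background ROI
bleaches at a rate similar to the signal ROI, so background subtraction alone
corrects the corrected trace for bleaching to first order. Time windows given
in seconds are half-open ``[start, end)`` and are mapped to frames by the
frame-start timestamp convention.
"""

from __future__ import annotations

import numpy as np

from .errors import NonNormalizableError
from .trace_io import CorrectedTrace, NormalizedTrace, RawTrace

__all__ = [
    "subtract_background",
    "moving_average",
    "normalize_dff",
    "window_to_frames",
    "window_slice",
    "pre_stim_stats",
]


def subtract_background(raw: RawTrace) -> CorrectedTrace:
    """Elementwise ROI minus background: F[k] = roi[k] - background[k]."""
    return CorrectedTrace(
        animal_id=raw.animal_id,
        time_s=raw.time_s,
        F=raw.roi - raw.background,
        protocol=raw.protocol,
    )


def window_to_frames(window_s: float, frame_rate_hz: float) -> int:
    """Convert a window length in seconds to frames (round half up, min 1)."""
    return max(1, int(np.floor(window_s * frame_rate_hz + 0.5)))


def moving_average(
    x: np.ndarray,
    *,
    window_frames: int | None = None,
    window_s: float | None = None,
    frame_rate_hz: float | None = None,
) -> np.ndarray:
    """Centered moving average with truncated edges.

    The window is ``window_frames`` samples wide (or ``round(window_s *
    frame_rate_hz)``, minimum 1); at the edges the mean is taken over the
    samples actually available, so the output has the input's length. For an
    even window the extra sample is taken from the trailing side.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("moving_average requires a non-empty 1-D array")
    if window_frames is None:
        if window_s is None or frame_rate_hz is None:
            raise ValueError("give window_frames, or window_s with frame_rate_hz")
        window_frames = window_to_frames(window_s, frame_rate_hz)
    w = int(window_frames)
    if w < 1:
        raise ValueError("window must be at least one frame")
    if w == 1:
        return x.copy()
    before = (w - 1) // 2
    after = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def window_slice(time_s: np.ndarray, start_s: float, end_s: float) -> slice:
    """Index slice of frames whose timestamps fall in [start_s, end_s)."""
    lo = int(np.searchsorted(time_s, start_s, side="left"))
    hi = int(np.searchsorted(time_s, end_s, side="left"))
    return slice(lo, hi)


def pre_stim_stats(c: CorrectedTrace) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of F over the pre-stimulation window."""
    sl = window_slice(c.time_s, 0.0, c.protocol.stim_start_s)
    seg = c.F[sl]
    if seg.size < 2:
        raise ValueError("pre-stimulation window must contain at least 2 frames")
    return float(seg.mean()), float(seg.std(ddof=1))


def normalize_dff(c: CorrectedTrace) -> NormalizedTrace:
    """Normalize to the mean pre-stimulation fluorescence F0.

    dff[k] = (F[k] - F0) / F0. By construction the mean of dff over the
    pre-stimulation window is zero, and the result is invariant under
    rescaling F by any positive constant.

    Raises
    ------
    NonNormalizableError
        If F0 <= 0 (background ROI at least as bright as the signal ROI).
    """
    f0, _ = pre_stim_stats(c)
    if f0 <= 0:
        raise NonNormalizableError(
            f"trace {c.animal_id!r}: pre-stimulation baseline F0 = {f0:g} <= 0"
        )
    return NormalizedTrace(
        animal_id=c.animal_id,
        time_s=c.time_s,
        dff=(c.F - f0) / f0,
        f0_baseline=f0,
        protocol=c.protocol,
    )
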