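"""Inclusion/exclusion logic for evoked-response traces.

Only traces with a clear light-evoked response can be fitted, so each animal
is classified before kinetics: the maximum of the background-corrected
fluorescence during stimulation (smoothed with a 1 s moving average) must
exceed the pre-stimulation mean by more than ``max(3 SD, 2 a.u.)`` — the
absolute floor guards against traces whose baseline is so quiet that 3 SD is
within camera noise. Animals whose fluorescence keeps increasing after the
stimulus, or that show threshold-crossing excursions before it (spontaneous
events), are excluded as well, as are traces whose constrained fits
degenerate (no increase during stimulation, or no decay afterwards).

The pre-stimulation mean/SD are computed on the raw (unsmoothed) corrected
trace with sample SD (ddof = 1); the module also exposes a vectorized null
calibrator for measuring the classifier's false-positive rate on pure-noise
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import moving_average, pre_stim_stats, window_slice, window_to_frames
from .trace_io import AcquisitionProtocol, CorrectedTrace

__all__ = [
    "ResponderParams",
    "ResponderVerdict",
    "classify_responder",
    "detect_exclusions",
    "apply_fit_exclusions",
    "null_responder_rate",
]

EXCLUSION_REASONS = (
    "no_response",
    "post_stim_increase",
    "spontaneous_event",
    "unfittable_rise",
    "no_decay",
)


@dataclass(frozen=True)
class ResponderParams:
    """Thresholds of the strong-responder cut-off.

    k_sd:
        SD multiplier on the pre-stimulation noise (default 3).
    min_abs_increase_au:
        Absolute floor on the required increase, in a.u. (default 2). Camera
        dependent: synthetic cohorts must use baseline/noise scales at which
        2 a.u. is a meaningful floor.
    response_window_s:
        Moving-average window for the in-stimulus maximum (default 1 s).
    spontaneous_window_s:
        Moving-average window for out-of-stimulus excursions (default 1 s).
    post_stim_margin_s:
        How far past stimulus end to scan for late increases; None means to
        the end of the trace.
    post_peak_grace_s:
        A post-stimulus maximum within this margin of stimulus end counts as
        part of the evoked response (the response peak commonly straddles
        the light-off boundary), not as a late increase.
    """

    k_sd: float = 3.0
    min_abs_increase_au: float = 2.0
    response_window_s: float = 1.0
    spontaneous_window_s: float = 1.0
    post_stim_margin_s: float | None = None
    post_peak_grace_s: float = 1.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.min_abs_increase_au < 0:
            raise ValueError("min_abs_increase_au must be >= 0")

    def threshold(self, pre_mean: float, pre_sd: float) -> float:
        return pre_mean + max(self.k_sd * pre_sd, self.min_abs_increase_au)


@dataclass(frozen=True)
class ResponderVerdict:
    """Classification outcome with audit diagnostics."""

    animal_id: str
    is_strong_responder: bool
    excluded: bool
    reasons: frozenset[str]
    pre_stim_mean_au: float
    pre_stim_sd_au: float
    stim_max_ma_au: float

    def __post_init__(self) -> None:
        reasons = frozenset(self.reasons)
        unknown = reasons - set(EXCLUSION_REASONS)
        if unknown:
            raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
        if self.excluded and not reasons:
            raise ValueError("an excluded verdict must carry reasons")
        if self.is_strong_responder and "no_response" in reasons:
            raise ValueError("a strong responder cannot carry no_response")
        object.__setattr__(self, "reasons", reasons)

    def with_reasons(self, *extra: str) -> "ResponderVerdict":
        reasons = self.reasons | set(extra)
        return replace(self, reasons=reasons, excluded=bool(reasons))


def _smoothed(c: CorrectedTrace, window_s: float) -> np.ndarray:
    return moving_average(
        c.F, window_s=window_s, frame_rate_hz=c.protocol.frame_rate_hz
    )


def classify_responder(c: CorrectedTrace, p: ResponderParams | None = None) -> ResponderVerdict:
    """Strong-responder test on a background-corrected trace.

    Let m, s be the mean and sample SD of F over the pre-stimulation window
    and M the maximum of the ``response_window_s`` moving average of F over
    the stimulation window; the animal is a strong responder iff
    ``M > m + max(k_sd * s, min_abs_increase_au)``.
    """
    p = p or ResponderParams()
    m, s = pre_stim_stats(c)
    proto = c.protocol
    sl = window_slice(c.time_s, proto.stim_start_s, proto.stim_end_s)
    M = float(_smoothed(c, p.response_window_s)[sl].max())
    strong = M > p.threshold(m, s)
    reasons = frozenset() if strong else frozenset({"no_response"})
    return ResponderVerdict(
        animal_id=c.animal_id,
        is_strong_responder=strong,
        excluded=not strong,
        reasons=reasons,
        pre_stim_mean_au=m,
        pre_stim_sd_au=s,
        stim_max_ma_au=M,
    )


def detect_exclusions(c: CorrectedTrace, p: ResponderParams | None = None) -> set[str]:
    """Trace-shape exclusions independent of the fits.

    ``post_stim_increase``: the smoothed post-stimulus maximum exceeds both
    the smoothed in-stimulus maximum and the responder threshold, and peaks
    later than ``post_peak_grace_s`` after light-off (the signal kept
    growing after the light went off; a peak straddling the boundary is
    part of the evoked response).
    ``spontaneous_event``: a smoothed pre-stimulus excursion crosses the
    responder threshold (activity not evoked by the stimulus). For this rule
    the baseline center and spread are estimated robustly (median and
    1.4826 MAD) — a spontaneous event sits inside the very window used to
    estimate the baseline, and would otherwise inflate its own threshold
    enough to mask itself.
    """
    p = p or ResponderParams()
    m, s = pre_stim_stats(c)
    thr = p.threshold(m, s)
    proto = c.protocol
    reasons: set[str] = set()

    smooth_resp = _smoothed(c, p.response_window_s)
    stim_sl = window_slice(c.time_s, proto.stim_start_s, proto.stim_end_s)
    stim_max = smooth_resp[stim_sl].max()
    post_end = (proto.duration_s if p.post_stim_margin_s is None
                else proto.stim_end_s + p.post_stim_margin_s)
    post_sl = window_slice(c.time_s, proto.stim_end_s, post_end)
    if post_sl.stop > post_sl.start:
        seg = smooth_resp[post_sl]
        k_max = int(np.argmax(seg))
        post_max = float(seg[k_max])
        t_peak = float(c.time_s[post_sl][k_max])
        late = t_peak >= proto.stim_end_s + p.post_peak_grace_s
        if late and post_max > stim_max and post_max > thr:
            reasons.add("post_stim_increase")

    smooth_spont = _smoothed(c, p.spontaneous_window_s)
    pre_sl = window_slice(c.time_s, 0.0, proto.stim_start_s)
    pre = c.F[pre_sl]
    m_rob = float(np.median(pre))
    s_rob = 1.4826 * float(np.median(np.abs(pre - m_rob)))
    if smooth_spont[pre_sl].max() > p.threshold(m_rob, s_rob):
        reasons.add("spontaneous_event")
    return reasons


def apply_fit_exclusions(
    verdict: ResponderVerdict,
    *,
    rise_degenerate: bool,
    no_decay: bool,
) -> ResponderVerdict:
    """Fold fit-stage failures back into the verdict.

    ``unfittable_rise``: the rise fit degenerated (plateau Max <= f0, i.e.
    no increase during stimulation). ``no_decay``: the post-stimulus window
    ends higher than it starts (an increase rather than a decay).
    """
    extra = []
    if rise_degenerate:
        extra.append("unfittable_rise")
    if no_decay:
        extra.append("no_decay")
    return verdict.with_reasons(*extra) if extra else verdict


def null_responder_rate(
    n_traces: int,
    protocol: AcquisitionProtocol,
    *,
    noise_sd_f_au: float,
    params: ResponderParams | None = None,
    seed: int = 0,
    block: int = 5000,
) -> float:
    """Empirical strong-responder rate on pure-noise corrected traces.

    Simulates ``n_traces`` white-Gaussian corrected traces (SD
    ``noise_sd_f_au``, the noise of ROI-minus-background) and applies the
    classify_responder rule vectorized. Used to calibrate the classifier's
    false-positive rate; matches classify_responder exactly on each trace.
    """
    p = params or ResponderParams()
    rng = np.random.default_rng(seed)
    t = protocol.times()
    pre_sl = window_slice(t, 0.0, protocol.stim_start_s)
    stim_sl = window_slice(t, protocol.stim_start_s, protocol.stim_end_s)
    w = window_to_frames(p.response_window_s, protocol.frame_rate_hz)
    before, after = (w - 1) // 2, w // 2
    n_frames = protocol.n_frames
    idx = np.arange(n_frames)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after, n_frames - 1)
    counts = hi - lo + 1

    hits = 0
    done = 0
    while done < n_traces:
        b = min(block, n_traces - done)
        F = rng.normal(0.0, noise_sd_f_au, (b, n_frames))
        csum = np.concatenate([np.zeros((b, 1)), np.cumsum(F, axis=1)], axis=1)
        ma = (csum[:, hi + 1] - csum[:, lo]) / counts
        m = F[:, pre_sl].mean(axis=1)
        s = F[:, pre_sl].std(axis=1, ddof=1)
        M = ma[:, stim_sl].max(axis=1)
        thr = m + np.maximum(p.k_sd * s, p.min_abs_increase_au)
        hits += int((M > thr).sum())
        done += b
    return hits / n_traces
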