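"""Plateau-constrained one-phase exponential fits and response statistics.

The rise during stimulation and the decay after it are each fitted with a
single free parameter, the time constant tau; the plateau levels are fixed
from the data beforehand, following the convention of standard curve-fitting
practice for evoked dF/F0 traces:

rise (during stimulation)
    ``f(t) = f0 + (Max - f0) (1 - exp(-(t - t0)/tau))`` with ``f0 = 0``,
    ``t0`` the first frame time at/after stimulus onset, and ``Max`` the
    maximum of the five-frame moving average of dF/F0 during stimulation or
    immediately (1 s) after it.
decay (after stimulation)
    ``f(t) = (f0 - Min) exp(-(t - t0)/tau) + Min`` with ``t0`` the first
    frame time at/after stimulus end, ``f0 = Max`` (same smoothed maximum),
    and ``Min`` the minimum of the 5 s moving average of dF/F0 after
    stimulation.

tau is found by unweighted least squares via bounded scalar minimization
(eight log-spaced sub-brackets, tolerance 1e-10) over
``[frame interval, 10 x window length]``; a one-dimensional problem, so the
result can be verified against an exhaustive grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateFitError, UndefinedRFError
from .preprocess import moving_average, window_slice
from .trace_io import NormalizedTrace

__all__ = [
    "FitResult",
    "AmplitudeResult",
    "RFResult",
    "fit_rise",
    "fit_decay",
    "compute_amplitude",
    "compute_rf",
    "smoothed_max",
    "smoothed_min",
]

#: "immediately after stimulation" margin used for the smoothed maximum (s).
MAX_MARGIN_S = 1.0
#: smoothing of the plateau maximum: five frame intervals (frames, not s).
MAX_WINDOW_FRAMES = 5
#: smoothing of the post-stimulus minimum: 5 s intervals.
MIN_WINDOW_S = 5.0


@dataclass(frozen=True)
class FitResult:
    """One constrained exponential fit.

    ``plateau`` is the fixed asymptote: Max for a rise, Min for a decay.
    ``f0`` is the fixed level at the time origin ``t0_s`` (0 for a rise, the
    smoothed maximum for a decay). ``sse`` is the sum of squared residuals
    over the fitted window, kept for downstream fit-quality screening.
    """

    kind: str
    tau_s: float
    f0: float
    plateau: float
    t0_s: float
    window: tuple[float, float]
    sse: float
    converged: bool
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dt = np.maximum(t - self.t0_s, 0.0)
        if self.kind == "rise":
            return self.f0 + (self.plateau - self.f0) * (1.0 - np.exp(-dt / self.tau_s))
        return (self.f0 - self.plateau) * np.exp(-dt / self.tau_s) + self.plateau


@dataclass(frozen=True)
class AmplitudeResult:
    """Mean dF/F0 over the reporter-mode amplitude window."""

    value: float
    window: tuple[float, float]
    sem_frames: float


@dataclass(frozen=True)
class RFResult:
    """Releasable fraction RF = F_MaxStim / F_NH4Cl (dimensionless)."""

    rf: float
    f_max_stim: float
    f_nh4cl: float


# ---------------------------------------------------------------------------
# plateau helpers
# ---------------------------------------------------------------------------

def smoothed_max(n: NormalizedTrace, *, margin_s: float = MAX_MARGIN_S) -> float:
    """Max of the five-frame moving average of dF/F0 during stimulation or
    immediately (``margin_s``) after it.

    The average is taken over the windowed segment only, so pre-stimulation
    baseline frames cannot leak into the plateau estimate.
    """
    proto = n.protocol
    sl = window_slice(n.time_s, proto.stim_start_s, proto.stim_end_s + margin_s)
    if sl.stop <= sl.start:
        raise DegenerateFitError("empty stimulation window")
    ma = moving_average(n.dff[sl], window_frames=MAX_WINDOW_FRAMES)
    return float(ma.max())


def smoothed_min(n: NormalizedTrace) -> float:
    """Min of the 5 s moving average of dF/F0 after stimulation
    (segment-local, as for smoothed_max)."""
    proto = n.protocol
    sl = window_slice(n.time_s, proto.stim_end_s, n.time_s[-1] + 1.0)
    if sl.stop <= sl.start:
        raise DegenerateFitError("empty post-stimulus window")
    ma = moving_average(n.dff[sl], window_s=MIN_WINDOW_S,
                        frame_rate_hz=proto.frame_rate_hz)
    return float(ma.min())


# ---------------------------------------------------------------------------
# 1-D least squares
# ---------------------------------------------------------------------------

def _sse(tau: float, t: np.ndarray, y: np.ndarray, f0: float, plateau: float,
         rising: bool) -> float:
    if rising:
        pred = f0 + (plateau - f0) * (1.0 - np.exp(-t / tau))
    else:
        pred = (f0 - plateau) * np.exp(-t / tau) + plateau
    r = y - pred
    return float(r @ r)

def _minimize_tau(t: np.ndarray, y: np.ndarray, f0: float, plateau: float,
                  rising: bool, lo: float, hi: float) -> tuple[float, float, bool]:
    """Bounded scalar minimization of the SSE over tau.

    Eight log-spaced sub-brackets of [lo, hi] are each minimized with
    bounded Brent (xatol 1e-10) and the best minimum is kept, guarding
    against flat/multimodal stretches of the 1-D objective.
    """
    edges = np.geomspace(lo, hi, 9)
    best_tau, best_sse, ok = lo, np.inf, False
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(
            _sse, bounds=(a, b), method="bounded",
            args=(t, y, f0, plateau, rising),
            options={"xatol": 1e-10},
        )
        if res.fun < best_sse:
            best_tau, best_sse, ok = float(res.x), float(res.fun), bool(res.success)
    return best_tau, best_sse, ok


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_rise(
    n: NormalizedTrace,
    *,
    max_override: float | None = None,
    window: tuple[float, float] | None = None,
) -> FitResult:
    """Fit the association time constant over the stimulation window.

    ``max_override`` substitutes a known plateau for the data-derived
    smoothed maximum (used for exact-recovery checks against the generator);
    ``window`` overrides the default ``[stim_start, stim_end)`` fit window.

    Raises
    ------
    DegenerateFitError
        If the plateau does not exceed f0 = 0 (no increase during
        stimulation); such animals are excluded upstream.
    """
    proto = n.protocol
    start, end = window if window is not None else (proto.stim_start_s, proto.stim_end_s)
    sl = window_slice(n.time_s, start, end)
    t = n.time_s[sl]
    y = n.dff[sl]
    if t.size < 3:
        raise DegenerateFitError("rise window holds fewer than 3 frames")
    f0 = 0.0
    plateau = smoothed_max(n) if max_override is None else float(max_override)
    if plateau - f0 <= 1e-12:
        raise DegenerateFitError(
            f"trace {n.animal_id!r}: rise plateau Max = {plateau:g} <= f0 = {f0:g}"
        )
    t0 = float(t[0])
    lo = 1.0 / proto.frame_rate_hz
    hi = 10.0 * (end - start)
    tau, sse, ok = _minimize_tau(t - t0, y, f0, plateau, True, lo, hi)
    return FitResult(kind="rise", tau_s=tau, f0=f0, plateau=plateau, t0_s=t0,
                     window=(start, end), sse=sse, converged=ok, n_points=t.size)


def fit_decay(
    n: NormalizedTrace,
    *,
    f0_override: float | None = None,
    min_override: float | None = None,
    window: tuple[float, float] | None = None,
) -> FitResult:
    """Fit the decay time constant over the post-stimulation window.

    f0 is the smoothed in/just-after-stimulus maximum and Min the smoothed
    post-stimulus minimum unless overridden.

    Raises
    ------
    DegenerateFitError
        If f0 <= Min (nothing to decay from, e.g. a flat post-stimulus
        segment).
    """
    proto = n.protocol
    start, end = (window if window is not None
                  else (proto.stim_end_s, n.time_s[-1] + 1.0 / proto.frame_rate_hz))
    sl = window_slice(n.time_s, start, end)
    t = n.time_s[sl]
    y = n.dff[sl]
    if t.size < 3:
        raise DegenerateFitError("decay window holds fewer than 3 frames")
    f0 = smoothed_max(n) if f0_override is None else float(f0_override)
    plateau = smoothed_min(n) if min_override is None else float(min_override)
    if f0 - plateau <= 1e-12:
        raise DegenerateFitError(
            f"trace {n.animal_id!r}: decay f0 = {f0:g} <= Min = {plateau:g}"
        )
    t0 = float(t[0])
    lo = 1.0 / proto.frame_rate_hz
    hi = 10.0 * (end - start)
    tau, sse, ok = _minimize_tau(t - t0, y, f0, plateau, False, lo, hi)
    return FitResult(kind="decay", tau_s=tau, f0=f0, plateau=plateau, t0_s=t0,
                     window=(start, end), sse=sse, converged=ok, n_points=t.size)


# ---------------------------------------------------------------------------
# amplitude and releasable fraction
# ---------------------------------------------------------------------------

def compute_amplitude(n: NormalizedTrace) -> AmplitudeResult:
    """Mean dF/F0 over the reporter-mode amplitude window.

    Green reporter: the last 5 s of stimulation (seconds 15-20 of the
    standard protocol). Red reporter: the first 1 s after stimulus end (the
    in-stimulus frames are unusable there because the actuation light
    contaminates the red channel).
    """
    proto = n.protocol
    if proto.reporter_mode == "phluorin":
        start = max(proto.stim_start_s, proto.stim_end_s - 5.0)
        end = proto.stim_end_s
    else:
        start = proto.stim_end_s
        end = proto.stim_end_s + 1.0
    if end > n.time_s[-1] + 1.0 / proto.frame_rate_hz + 1e-9:
        raise ValueError("amplitude window extends beyond the trace")
    sl = window_slice(n.time_s, start, end)
    seg = n.dff[sl]
    if seg.size == 0:
        raise ValueError("amplitude window holds no frames")
    sem = float(seg.std(ddof=1) / np.sqrt(seg.size)) if seg.size > 1 else np.nan
    return AmplitudeResult(value=float(seg.mean()), window=(start, end),
                           sem_frames=sem)


def compute_rf(
    n: NormalizedTrace,
    *,
    nh4cl_window: tuple[float, float] = (85.0, 90.0),
    smooth_window_s: float = 1.0,
) -> RFResult:
    """Releasable fraction: evoked maximum over total-pool (NH4Cl) level.

    ``f_max_stim`` is the maximum of the 1 s moving average of dF/F0 within
    the stimulation window; ``f_nh4cl`` is the mean dF/F0 over the NH4Cl
    reference window (85-90 s by default), during which the entire vesicular
    pool is dequenched.

    Raises
    ------
    UndefinedRFError
        If the protocol has no NH4Cl event covering the reference window, or
        the reference-level dF/F0 is not positive.
    """
    proto = n.protocol
    start, end = nh4cl_window
    covering = [
        (t, lab) for t, lab in proto.buffer_events
        if lab == "nh4cl" and t <= start
    ]
    if not covering:
        raise UndefinedRFError(
            f"protocol has no nh4cl buffer event at or before {start:g} s"
        )
    t_ev = covering[-1][0]
    later = [t for t, lab in proto.buffer_events if t > t_ev]
    if later and min(later) < end:
        raise UndefinedRFError(
            f"nh4cl phase ends before the reference window [{start:g}, {end:g}) s"
        )

    ma = moving_average(n.dff, window_s=smooth_window_s,
                        frame_rate_hz=proto.frame_rate_hz)
    stim_sl = window_slice(n.time_s, proto.stim_start_s, proto.stim_end_s)
    f_max_stim = float(ma[stim_sl].max())
    ref_sl = window_slice(n.time_s, start, end)
    if ref_sl.stop <= ref_sl.start:
        raise UndefinedRFError("no frames inside the NH4Cl reference window")
    f_nh4cl = float(n.dff[ref_sl].mean())
    if f_nh4cl <= 0:
        raise UndefinedRFError(
            f"NH4Cl reference dF/F0 = {f_nh4cl:g} <= 0; RF undefined"
        )
    return RFResult(rf=f_max_stim / f_nh4cl, f_max_stim=f_max_stim,
                    f_nh4cl=f_nh4cl)
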