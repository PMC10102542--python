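"""Ground-truth synthetic traces of a pH-sensitive vesicle-recycling reporter.

Two forward models generate RawTrace objects that look like in-vivo ROI
exports: a flat noisy baseline, an exponential rise toward a plateau while
the stimulation light is on, an exponential return to baseline afterwards,
slow photobleaching shared by the signal and background ROIs, and additive
Gaussian camera noise.

``phenomenological``
    The noiseless dF/F0 signal *is* the plateau-constrained one-phase
    association/decay shape that the kinetics module fits, so parameter
    recovery can be tested exactly. Pulsed stimulation reduces the effective
    drive by the duty cycle, which inflates the rise time constant by its
    inverse.
``mechanistic``
    A two-pool surface/vesicular model of the reporter. A fraction ``S`` of
    the reporter sits on the plasma membrane (neutral pH, bright) and
    ``V = 1 - S`` inside vesicles (acidic, brightness reduced to the quench
    factor ``q``). Light moves releasable vesicular reporter to the surface
    at rate ``k_exo = 1/tau_rise_s``; endocytosis returns evoked surface
    reporter to the releasable vesicular pool at ``k_endo = 1/tau_decay_s``,
    so sustained saturating light holds the whole releasable fraction ``rho``
    of the vesicular pool on the surface (a plateau) and the signal relaxes
    back to baseline after the light goes off. Buffer events reproduce the
    cultured-neuron assay: NH4Cl dequenches every pool (total-pool reference
    for the releasable fraction), a pH 5.6 acid buffer quenches the surface
    pool and drops fluorescence below baseline.

All randomness flows from explicit integer seeds; cohort generation derives
independent per-animal substreams from a master seed, so changing one
animal's draw never perturbs another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import IntegrationInstabilityError
from .trace_io import AcquisitionProtocol, RawTrace

__all__ = [
    "SimulationParams",
    "CohortSpec",
    "PoolState",
    "standard_protocol",
    "culture_protocol",
    "simulate_trace_phenomenological",
    "simulate_trace_mechanistic",
    "simulate_cohort",
    "DEFAULT_PARAMS_DISTRIBUTION",
]


@dataclass(frozen=True)
class SimulationParams:
    """Forward-model parameters for one animal/cell.

    Defaults emulate a wild-type green-reporter recording in cholinergic
    neurons: a 21% dF/F0 plateau, rise time constant 2.3 s, decay time
    constant 15.2 s, and camera noise sized so the pre-stimulation dF/F0
    fluctuates with SD ~ 0.02 at a 100 a.u. corrected baseline.

    amp:
        True dF/F0 plateau amplitude of the stimulus response (asymptote of
        the association). Non-responders have amp = 0.
    tau_rise_s, tau_decay_s:
        Association and decay time constants (s).
    baseline_au, background_au:
        Mean pre-stimulation corrected-signal and background-ROI levels (a.u.).
    bleach_rate_per_s:
        Shared exponential bleach rate applied to both ROI channels.
    noise_sd_au:
        Additive Gaussian noise SD per frame and channel (a.u.).
    photoswitch_amp, photoswitch_tau_s:
        Optional additive artifact for the red reporter: a transient of this
        dF/F0 amplitude decaying from stimulus end, present even without a
        functional actuator (no-ATR controls).
    releasable_fraction, quench_factor, surface_fraction_rest:
        Mechanistic mode only: fraction rho of the vesicular pool that the
        stimulus can release; relative brightness q of the quenched pool;
        resting surface fraction S0 of the reporter.
    """

    amp: float = 0.21
    tau_rise_s: float = 2.3
    tau_decay_s: float = 15.2
    baseline_au: float = 100.0
    background_au: float = 50.0
    bleach_rate_per_s: float = 1e-4
    noise_sd_au: float = 1.4
    responder: bool = True
    photoswitch_amp: float = 0.0
    photoswitch_tau_s: float = 5.0
    releasable_fraction: float = 0.2
    quench_factor: float = 0.05
    surface_fraction_rest: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")
        if not 0.0 <= self.releasable_fraction <= 1.0:
            raise ValueError("releasable_fraction must lie in [0, 1]")
        if not 0.0 <= self.quench_factor < 1.0:
            raise ValueError("quench_factor must lie in [0, 1)")
        if not 0.0 < self.surface_fraction_rest < 1.0:
            raise ValueError("surface_fraction_rest must lie in (0, 1)")

    @property
    def effective_amp(self) -> float:
        return self.amp if self.responder else 0.0


@dataclass(frozen=True)
class PoolState:
    """Surface (dequenched) and vesicular (quenched) reporter fractions."""

    S: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "V", V)
        if np.any(S < -1e-12) or np.any(V < -1e-12):
            raise ValueError("pool fractions must be non-negative")
        if np.max(np.abs(S + V - 1.0)) > 1e-9:
            raise ValueError("two-pool closure S + V = 1 violated")


def standard_protocol(
    *,
    frame_rate_hz: float = 5.0,
    baseline_s: float = 10.0,
    stim_s: float = 10.0,
    total_s: float = 90.0,
    stim_mode: str = "continuous",
    pulse_rate_hz: float | None = None,
    pulse_width_s: float | None = None,
    reporter_mode: str = "phluorin",
) -> AcquisitionProtocol:
    """In-vivo assay protocol: 10 s baseline, 10 s stimulus, 90 s total.

    The green-reporter assay runs at 5 fps (200 ms exposure); pass
    ``frame_rate_hz=20`` for the red-reporter assay (50 ms exposure).
    """
    return AcquisitionProtocol(
        frame_rate_hz=frame_rate_hz,
        n_frames=int(round(total_s * frame_rate_hz)),
        stim_start_s=baseline_s,
        stim_duration_s=stim_s,
        stim_mode=stim_mode,
        pulse_rate_hz=pulse_rate_hz,
        pulse_width_s=pulse_width_s,
        reporter_mode=reporter_mode,
    )


def culture_protocol(
    *,
    frame_rate_hz: float = 5.0,
    nh4cl_start_s: float = 60.0,
    acid_start_s: float | None = None,
    total_s: float = 95.0,
) -> AcquisitionProtocol:
    """Cultured-neuron quench/dequench protocol.

    10 s baseline and a 10 s stimulus as in vivo, then an NH4Cl (pH 7.4)
    buffer exchange that dequenches the entire vesicular pool — the
    releasable-fraction reference window is 85-90 s — optionally followed by
    a pH 5.6 acid buffer that quenches the surface pool.
    """
    events: list[tuple[float, str]] = [(nh4cl_start_s, "nh4cl")]
    if acid_start_s is not None:
        events.append((acid_start_s, "acid"))
    return AcquisitionProtocol(
        frame_rate_hz=frame_rate_hz,
        n_frames=int(round(total_s * frame_rate_hz)),
        stim_start_s=10.0,
        stim_duration_s=10.0,
        buffer_events=tuple(events),
        reporter_mode="phluorin",
    )


# ---------------------------------------------------------------------------
# phenomenological mode
# ---------------------------------------------------------------------------

def _phenomenological_dff(p: SimulationParams, protocol: AcquisitionProtocol,
                          t: np.ndarray) -> np.ndarray:
    """Noiseless dF/F0 signal: exactly the shape the kinetics module fits."""
    t_on = protocol.stim_start_s
    t_off = protocol.stim_end_s
    tau_rise_eff = p.tau_rise_s / protocol.duty_cycle
    amp = p.effective_amp
    dff = np.zeros_like(t)
    during = (t >= t_on) & (t < t_off)
    dff[during] = amp * (1.0 - np.exp(-(t[during] - t_on) / tau_rise_eff))
    level_end = amp * (1.0 - np.exp(-(t_off - t_on) / tau_rise_eff))
    after = t >= t_off
    dff[after] = level_end * np.exp(-(t[after] - t_off) / p.tau_decay_s)
    if protocol.reporter_mode == "phuji" and p.photoswitch_amp != 0.0:
        dff[after] += p.photoswitch_amp * np.exp(
            -(t[after] - t_off) / p.photoswitch_tau_s
        )
    return dff


def _to_raw(animal_id: str, t: np.ndarray, dff: np.ndarray,
            p: SimulationParams, protocol: AcquisitionProtocol) -> RawTrace:
    """Convert a noiseless dF/F0 signal to noisy two-channel a.u. data.

    Both channels bleach at the same rate (the basis for bleach correction by
    background subtraction); channel noise draws are independent.
    """
    rng = np.random.default_rng(p.seed)
    bleach = np.exp(-p.bleach_rate_per_s * t)
    roi = (p.background_au + p.baseline_au * (1.0 + dff)) * bleach
    background = p.background_au * bleach
    if p.noise_sd_au > 0:
        roi = roi + rng.normal(0.0, p.noise_sd_au, t.size)
        background = background + rng.normal(0.0, p.noise_sd_au, t.size)
    return RawTrace(animal_id=animal_id, time_s=t, roi=roi,
                    background=background, protocol=protocol)


def simulate_trace_phenomenological(
    p: SimulationParams,
    protocol: AcquisitionProtocol,
    *,
    animal_id: str = "sim",
) -> tuple[RawTrace, dict]:
    """Simulate one trace whose noiseless dF/F0 is the fit model itself.

    Returns the RawTrace plus a ground-truth record holding the generating
    parameters, the effective rise constant (inflated by the inverse duty
    cycle under pulsed stimulation), the plateau level actually reached at
    stimulus end, and the noiseless dF/F0 signal.
    """
    t = protocol.times()
    dff = _phenomenological_dff(p, protocol, t)
    raw = _to_raw(animal_id, t, dff, p, protocol)
    tau_rise_eff = p.tau_rise_s / protocol.duty_cycle
    truth = {
        "animal_id": animal_id,
        "mode": "phenomenological",
        "amp": p.effective_amp,
        "tau_rise_s": p.tau_rise_s,
        "tau_rise_eff_s": tau_rise_eff,
        "tau_decay_s": p.tau_decay_s,
        "level_end": p.effective_amp
        * (1.0 - np.exp(-protocol.stim_duration_s / tau_rise_eff)),
        "baseline_au": p.baseline_au,
        "background_au": p.background_au,
        "bleach_rate_per_s": p.bleach_rate_per_s,
        "noise_sd_au": p.noise_sd_au,
        "responder": p.responder,
        "seed": p.seed,
        "dff_true": dff,
    }
    return raw, truth


# ---------------------------------------------------------------------------
# mechanistic mode
# ---------------------------------------------------------------------------

def simulate_trace_mechanistic(
    p: SimulationParams,
    protocol: AcquisitionProtocol,
    *,
    animal_id: str = "sim",
    substeps_per_frame: int = 10,
    nh4cl_frame_interval_s: float | None = None,
) -> tuple[RawTrace, dict]:
    """Simulate one trace from the two-pool surface/vesicular model.

    The evoked surface excess ``e`` and the releasable vesicular pool ``v``
    obey ``de/dt = k_exo(t) v - k_endo e`` and ``dv/dt = -k_exo(t) v +
    k_endo e`` with ``k_exo = 1/tau_rise_s`` while the light is on (within
    pulses only, in pulsed mode) and ``k_endo = 1/tau_decay_s``; ``e + v``
    is conserved at ``rho * (1 - S0)``. The resting surface fraction S0 is
    held by the balanced spontaneous exo/endocytosis cycle, so the baseline
    is flat. Fluorescence is proportional to ``S + q V`` in saline,
    ``S + V`` under NH4Cl (all pools dequenched), and ``q (S + V)`` under the
    acid buffer (surface quenched too, dropping below baseline).

    Integration is fixed-step explicit Euler at ``substeps_per_frame`` times
    the frame rate (at least 10x); a step that drives any pool outside
    [0, 1] raises IntegrationInstabilityError. If ``nh4cl_frame_interval_s``
    is set, frames during buffer phases are thinned to one per interval
    (reduced acquisition rate to limit bleaching), and the returned trace
    carries a protocol with the reduced frame count.

    Returns the RawTrace plus a ground-truth record including the PoolState
    path sampled at the kept frames.
    """
    if substeps_per_frame < 10:
        raise ValueError("substeps_per_frame must be >= 10")
    n_sub = int(substeps_per_frame)
    dt = 1.0 / (protocol.frame_rate_hz * n_sub)
    n_steps = protocol.n_frames * n_sub
    t_grid = np.arange(n_steps) * dt

    k_exo = (1.0 / p.tau_rise_s) if p.responder else 0.0
    k_endo = 1.0 / p.tau_decay_s
    s0 = p.surface_fraction_rest
    pool = p.releasable_fraction * (1.0 - s0)

    light = protocol.light_on(t_grid)
    e = 0.0
    v = pool
    e_path = np.empty(n_steps)
    for i in range(n_steps):
        e_path[i] = e
        de = (k_exo * v if light[i] else 0.0) - k_endo * e
        e += de * dt
        v = pool - e
        if e < -1e-9 or v < -1e-9 or s0 + e > 1.0 + 1e-9:
            raise IntegrationInstabilityError(
                f"pool fraction left [0, 1] at t = {t_grid[i]:.3f} s; "
                f"decrease the integration step (dt = {dt:g} s)"
            )

    frame_idx = np.arange(protocol.n_frames) * n_sub
    t = t_grid[frame_idx]
    S = s0 + e_path[frame_idx]
    V = 1.0 - S

    q = p.quench_factor
    f_rel = np.empty_like(S)
    for k, tk in enumerate(t):
        buf = protocol.buffer_at(tk)
        if buf == "nh4cl":
            f_rel[k] = S[k] + V[k]
        elif buf == "acid":
            f_rel[k] = q * (S[k] + V[k])
        else:
            f_rel[k] = S[k] + q * V[k]
    baseline_rel = s0 + q * (1.0 - s0)
    dff_equiv = f_rel / baseline_rel - 1.0

    keep = np.ones(protocol.n_frames, dtype=bool)
    out_protocol = protocol
    if nh4cl_frame_interval_s is not None:
        last_kept = -np.inf
        for k, tk in enumerate(t):
            if protocol.buffer_at(tk) is None:
                last_kept = tk
                continue
            if tk - last_kept >= nh4cl_frame_interval_s - 1e-9:
                last_kept = tk
            else:
                keep[k] = False
        out_protocol = replace(protocol, n_frames=int(keep.sum()))

    raw = _to_raw(animal_id, t[keep], dff_equiv[keep], p, out_protocol)
    truth = {
        "animal_id": animal_id,
        "mode": "mechanistic",
        "releasable_fraction": p.releasable_fraction,
        "quench_factor": q,
        "surface_fraction_rest": s0,
        "tau_rise_s": p.tau_rise_s,
        "tau_decay_s": p.tau_decay_s,
        "baseline_au": p.baseline_au,
        "background_au": p.background_au,
        "bleach_rate_per_s": p.bleach_rate_per_s,
        "noise_sd_au": p.noise_sd_au,
        "responder": p.responder,
        "seed": p.seed,
        "pool_state": PoolState(S=S[keep], V=V[keep]),
        "dff_true": dff_equiv[keep],
    }
    return raw, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: between-animal variability of the wild-type-like study condition:
#: log-normal per parameter with the given (mean, CV).
DEFAULT_PARAMS_DISTRIBUTION: dict[str, tuple[float, float]] = {
    "amp": (0.21, 0.2),
    "tau_rise_s": (2.3, 0.2),
    "tau_decay_s": (15.2, 0.2),
    "baseline_au": (100.0, 0.2),
    "background_au": (50.0, 0.1),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``params_distribution`` maps SimulationParams field names to
    ``(mean, CV)`` of a log-normal between-animal distribution (log-normal
    keeps every parameter positive; CV 0.2 is typical animal-to-animal
    spread). Fields not listed are taken from ``base``. Each animal gets an
    independent random substream spawned from ``master_seed``.
    """

    n_animals: int
    protocol: AcquisitionProtocol
    responder_fraction: float = 1.0
    params_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS_DISTRIBUTION)
    )
    base: SimulationParams = field(default_factory=SimulationParams)
    mode: Literal["phenomenological", "mechanistic"] = "phenomenological"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0.0 or cv == 0.0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def simulate_cohort(spec: CohortSpec) -> tuple[list[RawTrace], pd.DataFrame]:
    """Generate a cohort of traces plus their ground-truth table.

    Per-animal parameters are drawn log-normally around the configured means;
    the responder flag is Bernoulli(responder_fraction). The ground-truth
    DataFrame records every drawn parameter (one row per animal).
    """
    children = np.random.SeedSequence(spec.master_seed).spawn(spec.n_animals)
    traces: list[RawTrace] = []
    rows: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        overrides: dict[str, float] = {}
        for name, (mean, cv) in spec.params_distribution.items():
            overrides[name] = _lognormal(rng, mean, cv)
        responder = bool(rng.random() < spec.responder_fraction)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(spec.base, **overrides, responder=responder,
                         seed=noise_seed)
        animal_id = f"a{i:04d}"
        if spec.mode == "phenomenological":
            raw, truth = simulate_trace_phenomenological(
                params, spec.protocol, animal_id=animal_id
            )
        else:
            raw, truth = simulate_trace_mechanistic(
                params, spec.protocol, animal_id=animal_id
            )
        traces.append(raw)
        truth = {k: v for k, v in truth.items()
                 if k not in ("dff_true", "pool_state")}
        rows.append(truth)
    return traces, pd.DataFrame(rows)
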