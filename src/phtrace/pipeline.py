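"""End-to-end per-animal analysis: raw trace -> result record.

Order of operations mirrors the manual workflow: background subtraction,
strong-responder classification and shape exclusions on the corrected trace
(a.u.), then dF/F0 normalization, amplitude, constrained rise/decay fits and
(when the protocol has an NH4Cl phase) the releasable fraction on the
normalized trace. Fit failures are folded back into the verdict as
exclusions; every exclusion decision is logged at info level with its
reason so filtering stays auditable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, NonNormalizableError, UndefinedRFError
from .kinetics import compute_amplitude, compute_rf, fit_decay, fit_rise
from .preprocess import moving_average, normalize_dff, subtract_background, window_slice
from .responder import (
    ResponderParams,
    apply_fit_exclusions,
    classify_responder,
    detect_exclusions,
)
from .trace_io import NormalizedTrace, RawTrace

__all__ = ["analyze_trace", "analyze_cohort"]

log = logging.getLogger("phtrace")


def _decay_is_increasing(n: NormalizedTrace, window_s: float = 1.0) -> bool:
    """True when the post-stimulus segment ends higher than it starts
    (terminal vs initial level of its 1 s smoothed trace)."""
    proto = n.protocol
    ma = moving_average(n.dff, window_s=window_s, frame_rate_hz=proto.frame_rate_hz)
    sl = window_slice(n.time_s, proto.stim_end_s, n.time_s[-1] + 1.0)
    seg = ma[sl]
    if seg.size < 2:
        return False
    return bool(seg[-1] > seg[0])


def analyze_trace(
    raw: RawTrace,
    *,
    responder_params: ResponderParams | None = None,
    apply_exclusions: bool = True,
    group: str | None = None,
) -> dict:
    """Analyze one animal; returns a write_results-compatible record.

    ``apply_exclusions=False`` (audit mode) still classifies and flags but
    fits every normalizable trace regardless of its verdict.
    """
    rp = responder_params or ResponderParams()
    corrected = subtract_background(raw)
    verdict = classify_responder(corrected, rp)
    shape_reasons = detect_exclusions(corrected, rp)
    if shape_reasons:
        verdict = verdict.with_reasons(*shape_reasons)

    record: dict = {
        "animal_id": raw.animal_id,
        "group": group,
        "pre_stim_mean_au": verdict.pre_stim_mean_au,
        "pre_stim_sd_au": verdict.pre_stim_sd_au,
        "stim_max_ma_au": verdict.stim_max_ma_au,
    }

    normalized: NormalizedTrace | None = None
    try:
        normalized = normalize_dff(corrected)
        record["f0_baseline_au"] = normalized.f0_baseline
    except NonNormalizableError:
        log.info("%s: baseline F0 <= 0, trace not normalizable", raw.animal_id)

    eligible = verdict.is_strong_responder and not verdict.excluded
    if normalized is not None:
        record["amplitude_dff"] = compute_amplitude(normalized).value
        if eligible or not apply_exclusions:
            rise_degenerate = False
            try:
                rise = fit_rise(normalized)
                record["tau_rise_s"] = rise.tau_s
                record["rise_sse"] = rise.sse
            except DegenerateFitError:
                rise_degenerate = True
            no_decay = _decay_is_increasing(normalized)
            if not no_decay:
                try:
                    decay = fit_decay(normalized)
                    record["tau_decay_s"] = decay.tau_s
                    record["decay_sse"] = decay.sse
                except DegenerateFitError:
                    log.info("%s: degenerate decay fit (flat segment)", raw.animal_id)
            verdict = apply_fit_exclusions(
                verdict, rise_degenerate=rise_degenerate, no_decay=no_decay
            )
        if any(lab == "nh4cl" for _, lab in raw.protocol.buffer_events):
            try:
                rf = compute_rf(normalized)
                record["rf"] = rf.rf
                record["f_max_stim"] = rf.f_max_stim
                record["f_nh4cl"] = rf.f_nh4cl
            except UndefinedRFError as err:
                log.info("%s: RF undefined (%s)", raw.animal_id, err)

    record["is_strong_responder"] = verdict.is_strong_responder
    record["excluded"] = verdict.excluded
    record["reasons"] = ";".join(sorted(verdict.reasons))
    if verdict.excluded:
        log.info("%s: excluded (%s)", raw.animal_id, record["reasons"])
    if apply_exclusions and verdict.excluded:
        # an excluded animal keeps its row but contributes no tau values
        record.pop("tau_rise_s", None)
        record.pop("rise_sse", None)
        record.pop("tau_decay_s", None)
        record.pop("decay_sse", None)
    return record


def analyze_cohort(
    traces,
    *,
    responder_params: ResponderParams | None = None,
    apply_exclusions: bool = True,
    group: str | None = None,
) -> pd.DataFrame:
    """Analyze a list of RawTraces into a tidy per-animal results frame."""
    records = [
        analyze_trace(tr, responder_params=responder_params,
                      apply_exclusions=apply_exclusions, group=group)
        for tr in traces
    ]
    df = pd.DataFrame(records)
    from .trace_io import RESULT_COLUMNS

    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RESULT_COLUMNS]
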