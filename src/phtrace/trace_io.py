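"""Trace containers and text-format I/O.

Every downstream module consumes only the types defined here. A recording is
described by an :class:`AcquisitionProtocol` (frame timing, stimulation window
and mode, optional buffer-exchange events) and carried through three stages:

``RawTrace``
    ROI and background-ROI mean fluorescence per frame, arbitrary units (a.u.),
    as exported by image-analysis software (e.g. ImageJ Multi Measure).
``CorrectedTrace``
    background-subtracted fluorescence ``F`` (a.u.).
``NormalizedTrace``
    dimensionless dF/F0 = (F - F0)/F0, where F0 is the mean of F over the
    pre-stimulation window.

File conventions
----------------
Trace tables are delimited text (comma or tab, auto-detected on read; commas
on write) with a header row. Frames are 1-based in files and 0-based
internally; the timestamp of frame ``k`` (0-based) is ``k / frame_rate_hz``,
i.e. frame start. Column pairs follow the ``Mean(<id>)`` / ``Bg(<id>)``
dialect by default; the pairing regexes are configurable because upstream
export layouts vary.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ProtocolError, TraceTableError

__all__ = [
    "AcquisitionProtocol",
    "RawTrace",
    "CorrectedTrace",
    "NormalizedTrace",
    "BUFFER_LABELS",
    "read_trace_table",
    "write_trace_table",
    "read_protocol",
    "write_protocol",
    "write_results",
    "read_results",
    "write_manifest",
    "RESULT_COLUMNS",
]

BUFFER_LABELS = ("nh4cl", "acid", "wash")

#: float formatting used by all writers: 12 significant digits round-trips
#: every value the pipeline produces.
_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, stimulation and buffer-event description of one recording.

    Parameters
    ----------
    frame_rate_hz:
        Acquisition rate in frames per second (20 fps for the red-reporter
        assay at 50 ms exposure, 5 fps for the green-reporter assay at
        200 ms exposure).
    n_frames:
        Total frame count of the recording.
    stim_start_s, stim_duration_s:
        Onset and length of the light stimulus, in seconds. The standard
        protocol applies a 10 s stimulus after 10 s of baseline.
    stim_mode:
        ``"continuous"`` or ``"pulsed"``. Pulsed mode delivers
        ``pulse_width_s`` pulses at ``pulse_rate_hz`` (e.g. 100 ms pulses at
        2 Hz, duty cycle 0.2).
    buffer_events:
        Ordered ``(time_s, label)`` pairs with label in ``{nh4cl, acid,
        wash}``; each event takes effect from its time until the next event
        (or the end of the recording). Used by the cultured-neuron
        quench/dequench assay.
    reporter_mode:
        ``"phluorin"`` (green; amplitude window = last 5 s of stimulation) or
        ``"phuji"`` (red; amplitude window = first 1 s after stimulation).
    """

    frame_rate_hz: float
    n_frames: int
    stim_start_s: float
    stim_duration_s: float
    stim_mode: str = "continuous"
    pulse_rate_hz: float | None = None
    pulse_width_s: float | None = None
    buffer_events: tuple[tuple[float, str], ...] = ()
    reporter_mode: str = "phluorin"

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ProtocolError("frame_rate_hz must be positive")
        if self.n_frames < 2:
            raise ProtocolError("n_frames must be >= 2")
        if self.stim_start_s < 0:
            raise ProtocolError("stim_start_s must be >= 0")
        if self.stim_duration_s <= 0:
            raise ProtocolError("stim_duration_s must be positive")
        if self.stim_start_s + self.stim_duration_s > self.duration_s + 1e-9:
            raise ProtocolError(
                "stimulation window extends beyond the recording "
                f"({self.stim_start_s + self.stim_duration_s:g} s > "
                f"{self.duration_s:g} s)"
            )
        if self.stim_mode not in ("continuous", "pulsed"):
            raise ProtocolError(f"unknown stim_mode {self.stim_mode!r}")
        if self.stim_mode == "pulsed":
            if self.pulse_rate_hz is None or self.pulse_rate_hz <= 0:
                raise ProtocolError("pulsed mode requires pulse_rate_hz > 0")
            if self.pulse_width_s is None or self.pulse_width_s <= 0:
                raise ProtocolError("pulsed mode requires pulse_width_s > 0")
            if self.pulse_width_s > 1.0 / self.pulse_rate_hz + 1e-12:
                raise ProtocolError(
                    "pulse_width_s must not exceed the pulse period"
                )
        if self.reporter_mode not in ("phluorin", "phuji"):
            raise ProtocolError(f"unknown reporter_mode {self.reporter_mode!r}")
        events = tuple((float(t), str(lab)) for t, lab in self.buffer_events)
        object.__setattr__(self, "buffer_events", events)
        last = -np.inf
        for t, lab in events:
            if lab not in BUFFER_LABELS:
                raise ProtocolError(f"unknown buffer label {lab!r}")
            if t <= last:
                raise ProtocolError("buffer_events must be strictly increasing in time")
            last = t

    # -- derived timing ----------------------------------------------------

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def stim_end_s(self) -> float:
        return self.stim_start_s + self.stim_duration_s

    @property
    def duty_cycle(self) -> float:
        """Fraction of the stimulation window during which light is on."""
        if self.stim_mode == "continuous":
            return 1.0
        return self.pulse_rate_hz * self.pulse_width_s

    def times(self) -> np.ndarray:
        """Frame-start timestamps: frame k (0-based) at k / frame_rate_hz."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def light_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: is the stimulation light on at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        in_stim = (t >= self.stim_start_s) & (t < self.stim_end_s)
        if self.stim_mode == "continuous":
            return in_stim
        phase = (t - self.stim_start_s) * self.pulse_rate_hz
        frac = phase - np.floor(phase)
        # guard against float representation error at pulse boundaries
        frac = np.where(frac >= 1.0 - 1e-9, 0.0, frac)
        in_pulse = frac < self.pulse_width_s * self.pulse_rate_hz - 1e-9
        return in_stim & in_pulse

    def buffer_at(self, t: float) -> str | None:
        """Label of the buffer event active at time ``t`` (None before the
        first event; ``wash`` restores the plain-saline condition)."""
        active = None
        for ev_t, lab in self.buffer_events:
            if t >= ev_t:
                active = lab
        return None if active == "wash" else active

    def to_dict(self) -> dict:
        d = {
            "frame_rate_hz": self.frame_rate_hz,
            "n_frames": self.n_frames,
            "stim_start_s": self.stim_start_s,
            "stim_duration_s": self.stim_duration_s,
            "stim_mode": self.stim_mode,
            "reporter_mode": self.reporter_mode,
        }
        if self.stim_mode == "pulsed":
            d["pulse_rate_hz"] = self.pulse_rate_hz
            d["pulse_width_s"] = self.pulse_width_s
        if self.buffer_events:
            d["buffer_events"] = [
                {"time_s": t, "label": lab} for t, lab in self.buffer_events
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        events = d.pop("buffer_events", [])
        parsed = []
        for ev in events:
            if isinstance(ev, dict):
                parsed.append((float(ev["time_s"]), str(ev["label"])))
            else:
                t, lab = ev
                parsed.append((float(t), str(lab)))
        return cls(
            frame_rate_hz=float(d["frame_rate_hz"]),
            n_frames=int(d["n_frames"]),
            stim_start_s=float(d["stim_start_s"]),
            stim_duration_s=float(d["stim_duration_s"]),
            stim_mode=str(d.get("stim_mode", "continuous")),
            pulse_rate_hz=(None if d.get("pulse_rate_hz") is None
                           else float(d["pulse_rate_hz"])),
            pulse_width_s=(None if d.get("pulse_width_s") is None
                           else float(d["pulse_width_s"])),
            buffer_events=tuple(parsed),
            reporter_mode=str(d.get("reporter_mode", "phluorin")),
        )


def read_protocol(path: str | Path) -> AcquisitionProtocol:
    """Load an AcquisitionProtocol from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ProtocolError(f"{path}: protocol file must be a mapping")
    return AcquisitionProtocol.from_dict(data)


def write_protocol(protocol: AcquisitionProtocol, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RawTrace:
    """One animal's ROI and background-ROI fluorescence time series (a.u.)."""

    animal_id: str
    time_s: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        time_s = _as_float_vector(self.time_s, "time_s")
        roi = _as_float_vector(self.roi, "roi")
        background = _as_float_vector(self.background, "background")
        n = self.protocol.n_frames
        if not (len(time_s) == len(roi) == len(background) == n):
            raise ValueError(
                f"trace {self.animal_id!r}: vector lengths "
                f"({len(time_s)}, {len(roi)}, {len(background)}) must all equal "
                f"protocol.n_frames = {n}"
            )
        if np.any(np.diff(time_s) <= 0):
            raise ValueError(f"trace {self.animal_id!r}: time_s must be strictly increasing")
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "roi", roi)
        object.__setattr__(self, "background", background)


@dataclass(frozen=True)
class CorrectedTrace:
    """Background-subtracted fluorescence F (a.u.; may go negative)."""

    animal_id: str
    time_s: np.ndarray
    F: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        F = _as_float_vector(self.F, "F")
        time_s = _as_float_vector(self.time_s, "time_s")
        if len(F) != self.protocol.n_frames or len(time_s) != self.protocol.n_frames:
            raise ValueError("CorrectedTrace length must equal protocol.n_frames")
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "F", F)


@dataclass(frozen=True)
class NormalizedTrace:
    """dF/F0 trace with its baseline F0 (mean pre-stimulation F, a.u.)."""

    animal_id: str
    time_s: np.ndarray
    dff: np.ndarray
    f0_baseline: float
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        dff = _as_float_vector(self.dff, "dff")
        time_s = _as_float_vector(self.time_s, "time_s")
        if self.f0_baseline <= 0:
            raise ValueError("f0_baseline must be positive")
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "dff", dff)


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------

#: default column dialect: "Mean(<id>)" = ROI, "Bg(<id>)" = background.
ROI_COLUMN_RE = re.compile(r"^Mean\((?P<id>.+)\)$")
BG_COLUMN_RE = re.compile(r"^Bg\((?P<id>.+)\)$")


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_trace_table(
    path: str | Path,
    protocol: AcquisitionProtocol,
    *,
    roi_pattern: re.Pattern | str = ROI_COLUMN_RE,
    bg_pattern: re.Pattern | str = BG_COLUMN_RE,
) -> list[RawTrace]:
    """Read a Multi-Measure-style trace table into per-animal RawTrace objects.

    The file is delimited text with a header; the first column is the 1-based
    frame index, followed by one ROI column and one background column per
    animal, paired via ``roi_pattern`` / ``bg_pattern`` (each with an ``id``
    group). Timestamps are computed as ``(frame - 1) / frame_rate_hz``.
    """
    roi_re = re.compile(roi_pattern)
    bg_re = re.compile(bg_pattern)
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text.splitlines()[0] if text else ",")
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise TraceTableError(f"{path}: empty trace table")
    header = [c.strip() for c in rows[0]]
    body = rows[1:]
    if len(body) != protocol.n_frames:
        raise TraceTableError(
            f"{path}: {len(body)} data rows but protocol.n_frames = {protocol.n_frames}"
        )
    width = len(header)
    for i, row in enumerate(body):
        if len(row) != width:
            raise TraceTableError(f"{path}: ragged row {i + 2} (expected {width} cells)")

    roi_cols: dict[str, int] = {}
    bg_cols: dict[str, int] = {}
    for j, name in enumerate(header):
        m = roi_re.match(name)
        if m:
            roi_cols[m.group("id")] = j
            continue
        m = bg_re.match(name)
        if m:
            bg_cols[m.group("id")] = j
    if not roi_cols:
        raise TraceTableError(f"{path}: no ROI columns matched the naming dialect")
    missing = sorted(set(roi_cols) - set(bg_cols))
    if missing:
        raise TraceTableError(
            f"{path}: ROI column(s) without a background pair: "
            + ", ".join(f"Mean({i})" for i in missing)
        )

    def column(j: int, name: str) -> np.ndarray:
        out = np.empty(len(body))
        for i, row in enumerate(body):
            cell = row[j].strip()
            try:
                out[i] = float(cell)
            except ValueError:
                raise TraceTableError(
                    f"{path}: non-numeric cell {cell!r} in column {name!r}, row {i + 2}"
                ) from None
        return out

    frames = column(0, header[0])
    expected = np.arange(1, protocol.n_frames + 1, dtype=float)
    if not np.array_equal(frames, expected):
        raise TraceTableError(
            f"{path}: frame column {header[0]!r} must run 1..{protocol.n_frames}"
        )
    time_s = (frames - 1.0) / protocol.frame_rate_hz

    traces = []
    for animal_id in roi_cols:
        traces.append(
            RawTrace(
                animal_id=animal_id,
                time_s=time_s,
                roi=column(roi_cols[animal_id], f"Mean({animal_id})"),
                background=column(bg_cols[animal_id], f"Bg({animal_id})"),
                protocol=protocol,
            )
        )
    return traces


def write_trace_table(traces: Sequence[RawTrace], path: str | Path) -> Path:
    """Write RawTraces as a comma-separated table readable by read_trace_table."""
    if not traces:
        raise ValueError("need at least one trace to write")
    n = traces[0].protocol.n_frames
    for tr in traces:
        if tr.protocol.n_frames != n:
            raise ValueError("all traces in one table must share a frame count")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["frame"]
        for tr in traces:
            header += [f"Mean({tr.animal_id})", f"Bg({tr.animal_id})"]
        writer.writerow(header)
        for k in range(n):
            row = [str(k + 1)]
            for tr in traces:
                row += [_FLOAT_FMT % tr.roi[k], _FLOAT_FMT % tr.background[k]]
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# per-animal results
# ---------------------------------------------------------------------------

#: stable column order of the results table; missing values are empty fields.
RESULT_COLUMNS = [
    "animal_id",
    "group",
    "is_strong_responder",
    "excluded",
    "reasons",
    "pre_stim_mean_au",
    "pre_stim_sd_au",
    "stim_max_ma_au",
    "f0_baseline_au",
    "amplitude_dff",
    "tau_rise_s",
    "rise_sse",
    "tau_decay_s",
    "decay_sse",
    "rf",
    "f_max_stim",
    "f_nh4cl",
]

_BOOL_COLUMNS = ("is_strong_responder", "excluded")


def _format_cell(key: str, value) -> str:
    if value is None:
        return ""
    if key in _BOOL_COLUMNS:
        return "true" if value else "false"
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return _FLOAT_FMT % value
    return str(value)


def write_results(records: Sequence[dict], path: str | Path) -> Path:
    """Write per-animal result records as CSV with a stable column order.

    Records are mappings keyed by RESULT_COLUMNS entries; absent or None/NaN
    values become empty fields. An empty record list yields a header-only file.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for rec in records:
            writer.writerow([_format_cell(k, rec.get(k)) for k in RESULT_COLUMNS])
    return path


def read_results(path: str | Path) -> list[dict]:
    """Read a results CSV back into records (inverse of write_results)."""
    numeric = {
        "pre_stim_mean_au", "pre_stim_sd_au", "stim_max_ma_au", "f0_baseline_au",
        "amplitude_dff", "tau_rise_s", "rise_sse", "tau_decay_s", "decay_sse",
        "rf", "f_max_stim", "f_nh4cl",
    }
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec: dict = {}
            for k, v in row.items():
                if v == "" or v is None:
                    rec[k] = None
                elif k in _BOOL_COLUMNS:
                    rec[k] = v == "true"
                elif k in numeric:
                    rec[k] = float(v)
                else:
                    rec[k] = v
            records.append(rec)
    return records


def write_manifest(path: str | Path, *, seed: int | None, config: dict,
                   outputs: Sequence[str | Path]) -> Path:
    """Write a JSON run manifest: config hash, seed, and produced files."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "outputs": [str(p) for p in outputs],
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
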