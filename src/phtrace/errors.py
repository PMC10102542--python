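"""Exception types raised by the trace-analysis pipeline."""


class PhtraceError(Exception):
    """Base class for all package-specific errors."""


class TraceTableError(PhtraceError):
    """Malformed trace table: ragged columns, unmatched ROI/background pairs,
    non-numeric cells, or a frame count that disagrees with the protocol."""


class ProtocolError(PhtraceError):
    """An AcquisitionProtocol violates its invariants."""


class NonNormalizableError(PhtraceError):
    """Pre-stimulation baseline F0 <= 0; typically the background ROI was
    brighter than the signal ROI."""


class DegenerateFitError(PhtraceError):
    """The constrained exponential fit has no admissible shape
    (rise: Max <= f0; decay: f0 <= Min)."""


class UndefinedRFError(PhtraceError):
    """Releasable fraction undefined: NH4Cl-phase normalized fluorescence <= 0."""


class IntegrationInstabilityError(PhtraceError):
    """Fixed-step integration of the two-pool model left [0, 1]; decrease the
    step size."""


class InsufficientDataError(PhtraceError):
    """Too few observations for the requested statistic."""
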