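"""Exception hierarchy for the gait pipeline."""


class GaitError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(GaitError, ValueError):
    """A generator or processing parameter violates its constraints."""


class SchemaError(GaitError, ValueError):
    """A trial bundle violates the canonical on-disk schema."""


class IngestError(GaitError, ValueError):
    """A foreign file (e.g. C3D) cannot be mapped onto a TrialRecord."""


class NoEventError(GaitError, ValueError):
    """No qualifying gait event could be detected."""


class InvalidEventError(GaitError, ValueError):
    """Event times violate their required ordering."""


class InvalidFilterError(GaitError, ValueError):
    """A filter specification is unrealisable (e.g. cutoff >= Nyquist)."""


class InvalidWindowError(GaitError, ValueError):
    """A smoothing window is inadmissible for the series length."""


class InvalidPhaseError(GaitError, ValueError):
    """A requested gait phase has an empty sample range."""


class InvalidAnthropometryError(GaitError, ValueError):
    """Anthropometry is missing or non-physical."""


class UndefinedNormalizationError(GaitError, ValueError):
    """Normalization is undefined (e.g. all-zero RMS values)."""


class FrameConstructionError(GaitError, ValueError):
    """A segment coordinate frame cannot be built from the markers."""


class DynamicsError(GaitError, ValueError):
    """Inverse dynamics inputs are inconsistent (e.g. missing CoP in stance)."""


class RangeError(GaitError, ValueError):
    """Requested events or windows fall outside the series extent."""


class DegenerateFitError(GaitError, ValueError):
    """A statistical model fit is degenerate (e.g. zero residual variance)."""
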