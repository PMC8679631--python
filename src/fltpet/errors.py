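"""Exception hierarchy for the fltpet pipeline.

Every anticipated failure mode raises a subclass of :class:`FltPetError`
so callers can trap pipeline errors without catching unrelated bugs.
"""


class FltPetError(ValueError):
    """Base class for all fltpet errors."""


class InvalidWindowError(FltPetError):
    """A time window does not intersect the frame schedule."""


class InvalidSubjectError(FltPetError):
    """Subject metadata (injected activity, body weight) is non-physical."""


class GeometryError(FltPetError):
    """Image / mask grids do not match, or a mask is empty."""


class InvalidBackgroundError(FltPetError):
    """A background (liver) denominator is zero or negative."""


class InvalidAIFError(FltPetError):
    """Parametric input-function parameters violate their invariants."""


class InvalidConfigError(FltPetError):
    """A configuration value is outside its admissible range."""


class RangeError(FltPetError):
    """A curve is asked for values outside its sampled support."""


class FitFailureError(FltPetError):
    """Every restart of a kinetic fit failed."""


class MaskConflictError(FltPetError):
    """Tissue-class masks overlap where they must be disjoint."""


class DegenerateROIError(FltPetError):
    """An ROI statistic is undefined (e.g. zero unfiltered mean)."""


class PairingError(FltPetError):
    """Paired cohorts have mismatched lengths."""


class SchemaError(FltPetError):
    """A fixture table does not match its documented schema."""


class DegenerateTestError(FltPetError):
    """A statistical test is undefined on the given data (all ties, zero marginal)."""


class UndefinedKappaError(FltPetError):
    """Cohen kappa is undefined because expected agreement equals 1."""


class NoDataError(FltPetError):
    """No evaluable records remain after exclusions."""
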