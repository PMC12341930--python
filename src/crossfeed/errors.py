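"""Exception hierarchy for the crossfeed package.

All package-raised errors derive from :class:`CrossfeedError` so callers
(including the CLI) can catch them uniformly; validation failures also derive
from :class:`ValueError` for ergonomic use in scripts.
"""


class CrossfeedError(Exception):
    """Base class for all crossfeed errors."""


class ValidationError(CrossfeedError, ValueError):
    """An input violates a documented precondition or type invariant."""


class NumericError(CrossfeedError, RuntimeError):
    """The ODE integrator or another numerical routine failed."""


class DegenerateDataError(CrossfeedError, ValueError):
    """The data carry no usable signal for the requested estimate (e.g. flat
    growth curves, or too few points above the detection floor)."""


class FittingError(CrossfeedError, RuntimeError):
    """All multistart attempts of a parameter fit failed."""


class CalibrationError(CrossfeedError, ValueError):
    """A fluorescence-to-OD calibration cannot be built (non-monotone data)."""


class SchemaError(CrossfeedError, ValueError):
    """A CSV or config file does not match its declared schema."""
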