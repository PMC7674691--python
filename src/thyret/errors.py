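"""Exception hierarchy for thyret."""


class ThyretError(Exception):
    """Base class for all thyret errors."""


class InvalidParameterError(ThyretError, ValueError):
    """A parameter value violates a model precondition."""


class InvalidDataError(ThyretError, ValueError):
    """Input data violate a precondition (non-positive samples, bad CSV, ...)."""


class InsufficientDataError(InvalidDataError):
    """Too few data points for the requested operation."""


class InvalidScenarioError(InvalidParameterError):
    """Unknown intake scenario or route/absorption-type combination."""


class InvalidSystemError(ThyretError, ValueError):
    """A compartment system is malformed (non-finite rates, missing thyroid)."""


class InsufficientGridError(ThyretError, ValueError):
    """The time grid does not cover the window required by an operation."""


class AlignmentError(InvalidDataError):
    """Two curves do not share the required common time points."""
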