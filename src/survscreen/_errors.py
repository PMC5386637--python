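"""Exception types shared across the package."""


class SurvScreenError(Exception):
    """Base class for package errors."""


class ValidationError(SurvScreenError, ValueError):
    """Invalid user input (bad shapes, ranges, or identifiers)."""


class DegenerateError(SurvScreenError):
    """A computation is undefined on this input (e.g. no cases at the horizon)."""


class ConvergenceError(SurvScreenError):
    """A model fit failed to converge or the likelihood is unbounded."""
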