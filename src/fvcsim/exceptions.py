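"""Exception hierarchy for fvcsim.

All computational failures raise FvcError subclasses so callers (and the CLI)
can distinguish validation problems from numerical ones.
"""


class FvcError(Exception):
    """Base class for all fvcsim errors."""


class ValidationError(FvcError, ValueError):
    """Invalid user input (bad field, bad plan request, bad config)."""


class DegenerateProjectionError(FvcError):
    """A point coincides with the source; beam's-eye-view is undefined."""


class NoIntersectionError(FvcError):
    """A ray misses the phantom, or a structure misses the dose grid."""


class ExtrapolationWarning(UserWarning):
    """A lookup table was queried outside its tabulated range and clamped."""
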