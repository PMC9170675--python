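"""Exception hierarchy for the FBST pipeline.

Every error raised by the library derives from :class:`FBSTError`, so
callers (and the command-line tool) can distinguish invalid usage from
genuine runtime failures with a single ``except`` clause.
"""


class FBSTError(Exception):
    """Base class for all errors raised by pyfbst."""


class InvalidInputError(FBSTError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSampleError(InvalidInputError):
    """The posterior draws have zero variance; no density can be estimated."""


class InvalidReferenceError(InvalidInputError):
    """A reference function is negative or otherwise not a valid r(theta)."""


class SupportMismatchError(FBSTError):
    """The reference function vanishes on a region carrying posterior mass."""


class NullOutsideSupportError(FBSTError):
    """The null value theta0 lies outside the evaluable grid range."""


class SamplerInitializationError(FBSTError):
    """The MCMC sampler could not evaluate the log-posterior at its start."""
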