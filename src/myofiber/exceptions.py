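"""Exception hierarchy shared across the package."""


class MyofiberError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(MyofiberError, ValueError):
    """Input violates a documented precondition (ordering, sizes, ranges)."""


class DegenerateTraceError(MyofiberError):
    """A decay trace cannot be normalized (zero or negative reference frame)."""


class NotFittedError(MyofiberError):
    """An operation requires a converged fit but received a failed one."""


class MissingBaselineError(MyofiberError):
    """A stratum has no rows in the baseline (vehicle) group."""


class UnclassifiableError(MyofiberError):
    """Fiber-type classification is undefined (all isoform abundances zero)."""
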