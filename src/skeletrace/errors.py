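"""Exception hierarchy shared by all skeletrace modules."""


class SkeletraceError(Exception):
    """Base class for all package errors."""


class ParameterError(SkeletraceError, ValueError):
    """An argument violates an operation's precondition."""


class VolumeFormatError(SkeletraceError, ValueError):
    """A volume file is unreadable or uses an unsupported MRC mode."""


class NumericError(SkeletraceError, ArithmeticError):
    """Non-finite data reached a numerical routine."""


class PackingError(SkeletraceError, RuntimeError):
    """Rejection sampling could not place the requested phantom objects."""
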