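"""Exception hierarchy shared across the package."""


class FusionACLError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FusionACLError, ValueError):
    """Invalid configuration value; the message names the offending key."""


class DataIOError(FusionACLError, IOError):
    """Dataset reading/writing failed (missing files, bad manifest rows)."""


class SizeError(FusionACLError, ValueError):
    """An array's spatial size violates an operation's precondition."""


class ExactModeError(FusionACLError, ValueError):
    """Exact enumeration requested for a model too large to enumerate."""


class UntrainedModelError(FusionACLError, RuntimeError):
    """Prediction requested from parameters that were never trained."""
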