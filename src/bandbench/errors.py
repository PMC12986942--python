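"""Exception hierarchy shared across the package."""


class BandbenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BandbenchError):
    """Invalid parameter combination (band outside Nyquist, bad spec, ...)."""


class ResolutionError(BandbenchError):
    """Frequency grid too coarse for the requested operation."""


class DataError(BandbenchError):
    """Input data violates a precondition (non-finite, too short, ...)."""


class DesignError(BandbenchError):
    """A filter design step produced an unusable (e.g. unstable) result."""


class FormatError(BandbenchError):
    """A file could not be parsed into the expected structure."""
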