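"""Exception hierarchy shared across the package."""


class RetsegError(Exception):
    """Base class for all package errors."""


class ChannelCountError(RetsegError):
    """Raised when an image does not have the expected number of channels."""


class DegenerateImageError(RetsegError):
    """Raised when an image or mask is empty / unusable (e.g. all-black input)."""


class ParameterError(RetsegError):
    """Raised for invalid numeric parameters (sigma <= 0, gamma <= 0, step > window, ...)."""


class ShapeError(RetsegError):
    """Raised when array shapes are inconsistent."""


class GridError(RetsegError):
    """Raised when patches do not match the patch grid they claim to come from."""


class DataError(RetsegError):
    """Raised for unusable datasets (missing labels, missing ground truth, ...)."""


class ConfigError(RetsegError):
    """Raised for malformed configuration documents (unknown keys, bad values)."""


class UndefinedMetricError(RetsegError):
    """Raised when a metric is undefined (zero denominator, single-class truth)."""
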