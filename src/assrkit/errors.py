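"""Exception types shared across the package."""


class AssrkitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AssrkitError, ValueError):
    """An argument violates a documented precondition."""


class EpochWindowError(AssrkitError, ValueError):
    """A requested time window does not fit inside the available data."""


class ChannelNotFoundError(AssrkitError, KeyError):
    """Requested channel label absent from a recording."""


class FormatError(AssrkitError, ValueError):
    """A file does not parse as the expected on-disk format."""


class DataIntegrityError(AssrkitError, ValueError):
    """Stored metadata and payload disagree (corrupt or tampered bundle)."""


class DegenerateDataError(AssrkitError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""
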