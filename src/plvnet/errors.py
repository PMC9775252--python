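"""Exception hierarchy shared across the pipeline stages."""


class PLVNetError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(PLVNetError, ValueError):
    """A frequency band is empty, negative, or outside the Nyquist range."""


class TooShortError(PLVNetError, ValueError):
    """A signal is too short for the requested operation (filter order,
    edge exclusion, minimum sample count)."""


class MissingChannelError(PLVNetError, KeyError):
    """Requested channel labels are absent from a recording."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"channels not present in recording: {self.missing}")


class InsufficientDataError(PLVNetError, ValueError):
    """A segmentation layout asks for more samples than the recording has."""


class ConfigurationError(PLVNetError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""


class DegenerateSignalError(PLVNetError, ValueError):
    """A signal has no oscillatory content (e.g. constant channel), so
    instantaneous phase is undefined."""
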