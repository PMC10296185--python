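"""Exception hierarchy shared across the package."""


class NirsGraphError(Exception):
    """Base class for all package-specific errors."""


class DataError(NirsGraphError):
    """Invalid or inconsistent input data (named file/participant/channel where possible)."""


class DegenerateFrameError(DataError):
    """A frame where at least one participant is at zero distance from every other.

    Closeness is infinite there; the analysis refuses to silently propagate it.
    """

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(
            message or f"degenerate frame {frame}: some participant has zero "
            "distance to every other participant (identical states)"
        )


class ConfigError(NirsGraphError):
    """Invalid configuration value."""
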