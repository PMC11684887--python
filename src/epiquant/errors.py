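"""Exception hierarchy for the pipeline.

Every error raised by epiquant derives from :class:`EpiquantError`, so callers
can catch the package's failures without masking programming errors.
"""


class EpiquantError(Exception):
    """Base class for all epiquant errors."""


class ConfigurationError(EpiquantError):
    """A configuration value violates its documented contract."""


class MissingChannelError(EpiquantError):
    """A required named channel is absent from an image or file."""

    def __init__(self, channel: str, available=None):
        self.channel = channel
        self.available = list(available) if available is not None else None
        msg = f"missing channel {channel!r}"
        if self.available is not None:
            msg += f" (available: {self.available})"
        super().__init__(msg)


class MalformedMapError(EpiquantError):
    """A probability-map file fails its normalization or shape contract."""


class DegenerateInputError(EpiquantError):
    """Input has no usable structure (e.g. constant scores, too few samples)."""


class PixelSizeError(EpiquantError):
    """Pixel size is neither present in file metadata nor overridden."""


class StageError(EpiquantError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
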