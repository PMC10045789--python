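"""Exception hierarchy shared by every stegowave module.

All failures raise a subclass of :class:`StegowaveError`; the CLI maps the
important ones to distinct exit codes so shell pipelines can branch on them.
"""


class StegowaveError(Exception):
    """Base class for every error raised by stegowave."""


class ContractError(StegowaveError, ValueError):
    """An argument violates a documented precondition (bad shape, range, ...)."""


class FormatError(StegowaveError):
    """Unsupported or malformed file format (16-bit image, bad magic, ...)."""


class CapacityError(StegowaveError):
    """Payload does not fit into the cover image.

    Carries ``required`` and ``available`` bit counts for diagnostics.
    """

    def __init__(self, required: int, available: int):
        self.required = int(required)
        self.available = int(available)
        super().__init__(
            f"payload needs {required} bits but the cover offers {available}"
        )


class CorruptionError(StegowaveError):
    """A compressed container failed its checksum or is truncated."""


class ConfigError(StegowaveError):
    """Inconsistent run configuration (e.g. lossless mode with a threshold)."""


class TruncationError(StegowaveError):
    """A bit stream ended before the declared number of symbols/bits."""


class IntegrityError(StegowaveError):
    """Internal consistency violated (e.g. a sentinel cell inside the image)."""


class EncodingError(StegowaveError, ValueError):
    """Payload text cannot be represented in 7-bit ASCII."""
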