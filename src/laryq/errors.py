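"""Error types shared across the pipeline stages."""


class LaryqError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(LaryqError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidParameterError(LaryqError, ValueError):
    """A configuration / parameter record is internally inconsistent."""


class RegionNotFoundError(LaryqError):
    """A segmentation stage could not locate its target structure."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"{region} not found")


class DegenerateContourError(LaryqError):
    """An active contour collapsed to zero area before it could be used."""
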