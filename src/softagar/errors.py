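"""Exception hierarchy for the softagar package."""


class SoftAgarError(Exception):
    """Base class for all softagar errors."""


class ConfigurationError(SoftAgarError):
    """Invalid simulation or run configuration (layout overflow, bad ranges...)."""


class DegenerateImageError(SoftAgarError):
    """An image that cannot be thresholded, e.g. constant inside the well."""


class FormatError(SoftAgarError):
    """Unreadable or malformed on-disk input (TIFF stacks, tables)."""


class AnalysisError(SoftAgarError):
    """A statistic that cannot be computed from the given data (missing
    controls, zero dynamic range, too few replicates)."""
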