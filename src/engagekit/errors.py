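"""Exception hierarchy used across the pipeline."""


class EngagekitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EngagekitError):
    """A configuration value is structurally invalid (bad backend name,
    image too small for the face template, classifier input below the
    receptive-field minimum, ...)."""


class EmptyInputError(EngagekitError):
    """A source yielded zero decodable frames."""


class ExtractionError(EngagekitError):
    """Landmark extraction failed on a frame; the frame is flagged
    no-face downstream instead of aborting the session."""


class DegenerateGeometryError(EngagekitError):
    """Landmark geometry does not admit normalization (coincident eye
    centroids)."""


class DataError(EngagekitError):
    """Input data violates its schema (missing columns, corrupt fixture)."""


class UndefinedMetricError(EngagekitError):
    """A metric's denominator is empty after applying the frame policy."""
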