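"""Exception hierarchy shared across the package."""


class RhizotraceError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RhizotraceError, ValueError):
    """Invalid geometric input (degenerate polyline, out-of-range arc length)."""


class ConfigurationError(RhizotraceError, ValueError):
    """Missing or inconsistent configuration (e.g. no pixel scale set)."""


class LabelParseError(RhizotraceError, ValueError):
    """A filename does not match the plate-image label convention."""


class RSMLError(RhizotraceError, ValueError):
    """Malformed or incomplete RSML document."""


class MergeError(RhizotraceError, ValueError):
    """Automatic and corrected root systems cannot be merged."""


class ValidationError(RhizotraceError, ValueError):
    """A domain object violates its structural invariants."""
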