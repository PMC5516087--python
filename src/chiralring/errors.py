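"""Exception hierarchy shared across the package."""


class ChiralRingError(Exception):
    """Base class for all package errors."""


class ParameterError(ChiralRingError, ValueError):
    """Invalid model or run parameters."""


class GenerationError(ChiralRingError, RuntimeError):
    """Initial-tissue construction failed after bounded retries."""


class GeometryError(ChiralRingError, ValueError):
    """Degenerate geometry: zero-length bond, <3-gon, self-intersection."""


class TopologyError(ChiralRingError, ValueError):
    """Inconsistent mesh connectivity or an ineligible topological move."""


class T1RejectedError(GeometryError):
    """A T1 flip was rolled back because it produced a self-intersection."""


class IntegrationError(ChiralRingError, RuntimeError):
    """Non-finite vertex positions encountered during time stepping."""


class TrackingError(ChiralRingError, ValueError):
    """A cell could not be followed through a trajectory."""


class DegenerateSeriesError(ChiralRingError, ValueError):
    """A statistic is undefined (zero variance, zero mean, empty count)."""


class NoRidgeError(ChiralRingError, RuntimeError):
    """No propagating correlation ridge could be identified."""


class LagRangeError(ChiralRingError, ValueError):
    """Requested lag range not covered by the correlation grid."""


class ConfigError(ChiralRingError, ValueError):
    """Malformed run configuration (unknown or invalid keys)."""
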