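"""Exception hierarchy for the odontometry pipeline."""


class AdoError(Exception):
    """Base class for all pipeline errors."""


class MeshFormatError(AdoError):
    """File could not be parsed as the requested mesh format."""


class EmptyMeshError(AdoError):
    """Mesh has no usable vertices or faces."""


class RepairError(AdoError):
    """Surface could not be brought to an edge-manifold state."""

    def __init__(self, message, offending_edges=()):
        super().__init__(message)
        self.offending_edges = list(offending_edges)


class UndersampledError(AdoError):
    """Too few neighbours inside the curvature radius at some vertex."""

    def __init__(self, message, vertex=None):
        super().__init__(message)
        self.vertex = vertex


class NoOcclusalSurfaceError(AdoError):
    """No closed high-curvature loop encircling a depression was found."""


class AmbiguousBorderError(AdoError):
    """More than one occlusal-border candidate with no unique best score."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class DegenerateFrameError(AdoError):
    """Border geometry does not define a tooth coordinate frame."""


class EllipseFitError(AdoError):
    """Point set does not admit a least-squares ellipse."""


class LandmarkError(AdoError):
    """Landmark detection failed on a section contour."""


class SplitError(AdoError):
    """Enamel-cap band contour could not be split at cervical edges."""


class EmptyReportError(AdoError):
    """No valid sections were available for aggregation."""


class SyntheticSpecError(AdoError):
    """Invalid parameters for the synthetic tooth generator."""


class ConfigError(AdoError):
    """Invalid pipeline configuration."""
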