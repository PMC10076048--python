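"""Exception types shared across the package."""


class PdflowError(Exception):
    """Base class for all package-specific errors."""


class SkeletonParseError(PdflowError):
    """Malformed or truncated NTU .skeleton file; message names the line."""


class SkeletonFormatError(PdflowError):
    """Structurally valid file with inconsistent declared counts."""


class ContainerError(PdflowError):
    """Dataset container (HDF5) is missing arrays or has bad shapes."""


class EmptySequenceError(PdflowError):
    """A pose sequence contains no usable (non-null) frames."""


class ConfigError(PdflowError):
    """Invalid configuration values (indices, frame counts, ...)."""


class DegenerateGeometryError(PdflowError):
    """Reference bones are zero or collinear; no rotation can be built."""


class ShapeError(PdflowError):
    """Array arguments have incompatible shapes."""


class UndefinedLossError(PdflowError):
    """A loss has no valid entries to average over."""


class UndefinedSimilarityError(PdflowError):
    """Cosine similarity is undefined for a zero-norm representation."""
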