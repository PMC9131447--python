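"""Exception types shared across the package."""


class StrifeError(Exception):
    """Base class for all package-specific errors."""


class GridFormatError(StrifeError):
    """A grid file is malformed (missing/invalid header field or values)."""


class UnsupportedGeometryError(StrifeError):
    """A volumetric map has non-cubic voxels or a non-orthogonal cell."""


class EmptyInputError(StrifeError):
    """An operation that requires a non-empty collection received none."""


class FragmentUnsuitableError(StrifeError):
    """Fragment heavy atoms fall outside the apolar hotspot envelope."""


class InvalidMoleculeError(StrifeError):
    """A molecule could not be parsed or sanitized."""


class InvalidElaborationError(StrifeError):
    """An elaboration subgraph is disconnected or otherwise malformed."""


class TooFewPairsError(StrifeError):
    """Not enough training pairs to fit the generative model."""


class UntrainedModelError(StrifeError):
    """A prediction was requested from a model that has not been fitted."""


class PoseFailureError(StrifeError):
    """3D embedding under the fragment constraint failed after retries."""
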