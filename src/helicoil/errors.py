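"""Exception hierarchy shared by all helicoil modules."""


class HelicoilError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HelicoilError):
    """A coordinate or config file could not be parsed."""


class EmptyModelError(HelicoilError):
    """A structure contained no usable CA atoms."""


class TopologyError(HelicoilError):
    """Trajectory frames do not share a common chain/residue/atom topology."""


class SelectionError(HelicoilError):
    """A requested chain/residue/atom is absent from the model."""


class AlignmentError(HelicoilError):
    """Series with incompatible indices were combined."""


class InsufficientInputError(HelicoilError):
    """Too few residues/atoms for the requested geometric construction."""


class DegenerateGeometryError(HelicoilError):
    """Geometry is singular (coincident points, zero-length projections)."""


class UnderdeterminedError(HelicoilError):
    """Fewer than three atoms for a rigid superposition."""


class WindowError(HelicoilError):
    """Requested trajectory window exceeds the trajectory span."""


class ClashError(HelicoilError):
    """Generated geometry contains inter-chain steric clashes."""


class ConfigError(HelicoilError):
    """An analysis configuration is inconsistent with the input topology."""
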