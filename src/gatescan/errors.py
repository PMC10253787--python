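"""Exception types raised across the package."""


class GatescanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GatescanError):
    """A structure or trajectory file could not be parsed."""


class EmptyStructureError(GatescanError):
    """A parsed model contains no atoms."""


class TopologyError(GatescanError):
    """Topology and trajectory disagree (e.g. atom-count mismatch)."""


class PartialReadError(GatescanError):
    """A trajectory file ended early; carries the frames recovered so far."""

    def __init__(self, message, n_frames_recovered=0, trajectory=None):
        super().__init__(message)
        self.n_frames_recovered = n_frames_recovered
        self.trajectory = trajectory


class EmptySelectionError(GatescanError):
    """A selection spec matched no atoms."""


class SpecError(GatescanError):
    """A synthetic-channel spec is invalid or geometrically impossible."""


class DegenerateFitError(GatescanError):
    """Fewer than 3 non-collinear atoms available for superposition."""


class AlignmentError(GatescanError):
    """Two per-residue or per-bond profiles cover different residue sets."""


class ConfigurationError(GatescanError):
    """The input lacks information an analysis needs (e.g. no hydrogens)."""
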