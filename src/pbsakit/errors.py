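"""Exception hierarchy for pbsakit."""


class PbsakitError(Exception):
    """Base class for all package errors."""


class SchemaError(PbsakitError):
    """Input file does not conform to the documented schema."""


class ValidationError(PbsakitError):
    """Input values violate a domain invariant."""


class GroupLookupError(PbsakitError):
    """A named index group does not exist."""


class TrajectoryFormatError(PbsakitError):
    """Trajectory file is malformed or inconsistent between frames."""


class EmptyInputError(PbsakitError):
    """An input that must contain data is empty."""


class SingularityError(PbsakitError):
    """Two interacting atoms coincide (r_ij = 0)."""


class ConvergenceError(PbsakitError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class GridSizeError(PbsakitError):
    """Requested PB grid exceeds the configured node budget."""


class InsufficientDataError(PbsakitError):
    """Statistic requested on too few observations."""


class UnsupportedResidueError(PbsakitError):
    """Residue cannot be truncated to alanine (GLY/PRO/ALA or no CB)."""


class ScopeError(PbsakitError):
    """Operation requested outside its allowed scope (e.g. ligand mutation)."""


class StateError(PbsakitError):
    """Operation requires state (e.g. resolved groups) that is absent."""


class ResultsCompatibilityError(PbsakitError):
    """Results file was written by an incompatible version."""
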