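"""Exception hierarchy.

``ValidationError`` covers bad inputs/parameters (CLI exit code 1),
``ComputationError`` covers failures of the numerical machinery itself
(CLI exit code 2).
"""


class RssiNwuError(Exception):
    """Base class for all package errors."""


class ValidationError(RssiNwuError, ValueError):
    """Invalid input data, parameters, or configuration."""


class FormatError(ValidationError):
    """Malformed or unsupported file content."""


class AlignmentError(ValidationError):
    """Two grids that must share geometry do not."""


class DomainError(ValidationError):
    """Value outside the mathematical domain of an operation."""


class OutOfRangeError(ValidationError):
    """Value outside the supported study range."""


class ComputationError(RssiNwuError, RuntimeError):
    """A numerical procedure failed at run time."""


class EmptySelectionError(ComputationError):
    """An operation produced or received an empty voxel selection."""


class ConvergenceError(ComputationError):
    """Iterative optimization did not converge within its budget."""

    def __init__(self, message: str, final_metric: float | None = None):
        super().__init__(message)
        self.final_metric = final_metric


class UndefinedStatisticError(ComputationError):
    """A statistic is mathematically undefined for the given data."""


class PipelineStageError(ComputationError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
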