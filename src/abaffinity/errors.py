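"""Exception hierarchy.

Errors are grouped by how the CLI maps them to exit codes: usage problems
(click handles those), data problems (:class:`DataError` subclasses, exit 3)
and numerical failures (:class:`NumericalError` subclasses, exit 4).
"""


class AbaffinityError(Exception):
    """Base class for all package errors."""


class DataError(AbaffinityError):
    """Input data is malformed, inconsistent or missing."""


class FormatError(DataError):
    """Structure or table content could not be parsed."""


class EmptyStructureError(DataError):
    """A model or selection contains no atoms."""


class ChainLookupError(DataError):
    """A requested chain id does not exist in the structure."""


class ValidationError(DataError):
    """An argument violates a precondition (overlapping sets, bad range...)."""


class ClassificationError(DataError):
    """A residue name is not covered by the classification table."""


class ParameterisationError(DataError):
    """No parameter (e.g. vdW radius) is available for an atom."""


class DegenerateSurfaceError(DataError):
    """A surface-based quantity is undefined (e.g. zero NIS residues)."""


class AlignmentError(DataError):
    """No usable residue mapping between two chains."""


class GenerationError(DataError):
    """A synthetic fixture specification could not be realised."""


class CalibrationError(DataError):
    """A detector calibration run is unusable."""


class NumericalError(AbaffinityError):
    """A numerical routine failed to produce a valid result."""


class DomainError(NumericalError):
    """Inputs fall outside the mathematical domain of a formula."""


class SolverError(NumericalError):
    """Root finding or least squares did not converge."""


class FitError(SolverError):
    """Peak deconvolution did not converge; carries fit diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
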