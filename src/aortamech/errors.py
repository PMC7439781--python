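"""Exception hierarchy for the aortamech pipeline.

All package-specific failures derive from :class:`AortamechError` so callers
can catch pipeline problems without masking programming errors.
"""


class AortamechError(Exception):
    """Base class for all aortamech failures."""


class InvalidKinematicsError(AortamechError):
    """Deformation input is kinematically inadmissible (non-SPD tensor,
    non-positive stretch, ...)."""


class OutOfRangeDeformationError(AortamechError):
    """A strain-energy exponential overflowed; the offending invariant is
    reported in the message."""


class FitFailureError(AortamechError):
    """Material-parameter fit did not converge.

    Carries the best iterate and residual norm when available."""

    def __init__(self, message, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


class DegenerateDataError(AortamechError):
    """Input data carry no usable variance (constant sample, n too small)."""


class NonConvergenceError(AortamechError):
    """An iterative solve failed; carries bracket / trace diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IncompatibleStateError(AortamechError):
    """Two deformed states do not share a reference geometry."""


class NonphysicalViscosityError(AortamechError):
    """Blood viscosity formula produced a non-positive value."""


class StructuralRangeError(AortamechError):
    """Flow solve drove the wall outside its admissible pressure-area range."""


class CalibrationError(NonConvergenceError):
    """An inverse-calibration stage failed; carries the iteration trace."""


class InfeasibleTargetError(AortamechError):
    """A calibration target is unreachable (e.g. systolic volume below the
    diastolic volume)."""


class ConfigurationError(AortamechError):
    """Invalid run configuration or cohort specification."""
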