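"""Exception hierarchy for the npuptake pipeline.

Every anticipated failure mode raises a subclass of :class:`NpUptakeError`
so that callers (and the CLI driver) can distinguish pipeline errors from
programming bugs.
"""


class NpUptakeError(Exception):
    """Base class for all npuptake errors."""


class InvalidOvertoneError(NpUptakeError):
    """Overtone number is not an odd positive integer."""


class DegenerateLayerError(NpUptakeError):
    """Film with finite thickness but zero viscosity and zero shear modulus."""


class EmptyTraceError(NpUptakeError):
    """A QCM trace with no time points was supplied."""


class InsufficientDataError(NpUptakeError):
    """Too few observations for the requested estimate."""


class UnderdeterminedError(NpUptakeError):
    """Fewer observations than free parameters in a fit."""


class FitFailureError(NpUptakeError):
    """Optimizer failed to converge from every start point.

    Carries ``best_residual`` when at least one start produced a candidate.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class InvalidReferenceError(NpUptakeError):
    """Reference mass (SVL mass before uptake) is not positive."""


class NoUptakeError(NpUptakeError):
    """Nanoparticle mass change is not positive; a count ratio is undefined."""


class MissingReferenceError(NpUptakeError):
    """The zero-cholesterol reference condition is absent from a trend input."""


class AllCensoredError(NpUptakeError):
    """No uncensored anchoring events; only a lower bound on tau exists.

    Carries ``tau_lower``, the one-sided confidence lower bound.
    """

    def __init__(self, message: str, tau_lower: float | None = None):
        super().__init__(message)
        self.tau_lower = tau_lower


class ConditionMismatchError(NpUptakeError):
    """No shared cholesterol conditions between two per-condition inputs."""


class DegenerateIntensityError(NpUptakeError):
    """Polarized intensities with a non-positive anisotropy denominator."""


class SingularDesignError(NpUptakeError):
    """Regression design matrix is singular (e.g. all x equal)."""


class SchemaError(NpUptakeError):
    """Input table violates the expected column schema or row constraints."""


class ConfigError(NpUptakeError):
    """Invalid or inconsistent scenario / pipeline configuration."""
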