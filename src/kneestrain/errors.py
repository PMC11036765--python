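"""Exception hierarchy shared across the package."""


class KneeStrainError(Exception):
    """Base class for all kneestrain errors."""


class ConfigurationError(KneeStrainError):
    """Unknown or inconsistent configuration option."""


class SchemaError(KneeStrainError):
    """Malformed model JSON. Carries a JSON-pointer-style location."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


class ModelValidationError(KneeStrainError):
    """A model field violates a structural invariant (e.g. non-rotation matrix)."""


class ParameterError(KneeStrainError):
    """Constitutive parameter out of its admissible range."""


class StateError(KneeStrainError):
    """Operation requires initialization that has not been performed."""


class DegenerateGeometryError(KneeStrainError):
    """Coincident insertion points or otherwise singular geometry."""


class SolverError(KneeStrainError):
    """Static solve failed to converge, or dynamic integration went unstable."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class InsufficientDataError(KneeStrainError):
    """Too few samples/points for the requested statistic."""


class CohortSpecError(KneeStrainError):
    """Infeasible synthetic-cohort specification."""
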