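"""Exception hierarchy for ctgsvm.

All package errors derive from :class:`CTGSVMError` so callers can catch a
single base class; most also derive from ``ValueError`` because they signal
invalid caller input rather than internal failure.
"""


class CTGSVMError(Exception):
    """Base class for all ctgsvm errors."""


class DimensionError(CTGSVMError, ValueError):
    """Vectors or matrices have incompatible shapes."""


class DomainError(CTGSVMError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class ValidationError(CTGSVMError, ValueError):
    """Input data failed validation (non-finite values, bad schema, ...)."""


class DegenerateInputError(CTGSVMError, ValueError):
    """Training input is degenerate (e.g. a single class present)."""


class ConditioningError(CTGSVMError, ArithmeticError):
    """The KKT linear system is numerically singular or the solve failed."""


class StratificationError(CTGSVMError, ValueError):
    """A class is too small for the requested number of folds."""


class NormalizationError(CTGSVMError, ValueError):
    """A confusion-matrix column is empty and cannot be normalized."""


class UndefinedRateError(CTGSVMError, ValueError):
    """Sensitivity or specificity has a zero denominator."""


class PlanError(CTGSVMError, ValueError):
    """A class-partition plan violates the binary-tree invariants."""


class SchemaError(CTGSVMError, ValueError):
    """An input table is missing a required column."""


class EmptyDatasetError(CTGSVMError, ValueError):
    """No valid rows survived parsing."""


class FitnessEvaluationError(CTGSVMError):
    """Fitness evaluation failed; carries the offending position."""

    def __init__(self, message: str, position=None):
        super().__init__(message)
        self.position = position
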