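"""Exception hierarchy shared across the package."""


class TDBSCANError(Exception):
    """Base class for all package errors."""


class ValidationError(TDBSCANError, ValueError):
    """Invalid argument values (out-of-range coordinates, bad parameters)."""


class ContractViolationError(TDBSCANError):
    """A documented precondition of an operation was violated by the caller."""


class UnsupportedRegionError(TDBSCANError):
    """Dataset spans the antimeridian; wraparound indexing is unsupported."""


class UndefinedMetricError(TDBSCANError):
    """A clustering-validity metric is undefined for the given labeling."""


class SchemaError(TDBSCANError):
    """Input table is missing required columns."""


class EmptyInputError(TDBSCANError):
    """No valid rows remained after parsing and filtering."""
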