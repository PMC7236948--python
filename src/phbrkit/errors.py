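"""Exception hierarchy.

Every error raised by this package derives from :class:`PhbrKitError` so callers
can catch pipeline failures distinctly from programming errors.
"""


class PhbrKitError(Exception):
    """Base class for all phbrkit errors."""


class InvalidSequenceError(PhbrKitError, ValueError):
    """A nucleotide or amino-acid sequence failed validation."""


class ReferenceMismatchError(PhbrKitError, ValueError):
    """A variant's stated reference does not match the transcript.

    Usually signals a stale transcript mapping between the variant table and
    the CDS FASTA.
    """


class UnsupportedVariantError(PhbrKitError, ValueError):
    """Variant class outside the supported set (missense, in-frame indel)."""


class InvalidInputError(PhbrKitError, ValueError):
    """Generic invalid argument (out-of-range position, empty protein, ...)."""


class EmptyInputError(PhbrKitError, ValueError):
    """An operation that requires a nonempty collection received an empty one."""


class ArityError(PhbrKitError, ValueError):
    """Wrong number of elements (e.g. an HLA genotype without six slots)."""


class DomainError(PhbrKitError, ValueError):
    """A numeric argument outside the mathematical domain of the operation."""


class MissingPredictionError(PhbrKitError, KeyError):
    """A rank-table oracle was queried for an (allele, peptide) pair it lacks."""


class TableParseError(PhbrKitError, ValueError):
    """A tabular input file is malformed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(PhbrKitError, ValueError):
    """An input table is missing required columns."""


class PatientNotEvaluableError(PhbrKitError, ValueError):
    """A patient has no scored mutation, so min-PHBR is undefined."""


class DegenerateModelError(PhbrKitError, ValueError):
    """A statistical model cannot be fit (e.g. no events in a stratum)."""


class UndefinedEstimateError(PhbrKitError, ValueError):
    """An estimator is undefined for the given table (e.g. zero numerator cell)."""


class ConfigError(PhbrKitError, ValueError):
    """Inconsistent or incomplete run/simulation configuration."""
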