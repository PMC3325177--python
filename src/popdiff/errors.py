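"""Exception hierarchy.

Errors are split into configuration/parameter problems (:class:`ParameterError`,
:class:`SchemaError`) and data problems discovered at run time
(:class:`DataError` and subclasses), so a CLI can map them onto distinct
exit codes.
"""


class PopdiffError(Exception):
    """Base class for all package errors."""


class ParameterError(PopdiffError, ValueError):
    """A parameter is outside its documented domain."""


class SchemaError(PopdiffError):
    """An input file does not conform to the expected schema."""


class DataError(PopdiffError):
    """The data are structurally valid but unusable for the requested operation."""


class MissingDataError(DataError, KeyError):
    """A requested rsid / population / region is absent from a table."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class IncompatibleAllelesError(DataError):
    """Study alleles cannot be reconciled with the reference alleles."""


class InsufficientControlsError(DataError):
    """A frequency-matched control pool is smaller than the required minimum."""


class InsufficientDataError(DataError):
    """Too few usable records for the requested statistic."""
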