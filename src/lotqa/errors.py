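"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so that scripted callers can
tell a bad parameter from a malformed file from an undefined statistic.
"""


class LotQAError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LotQAError, ValueError):
    """A simulation or analysis parameter violates its stated range."""


class ValidationError(LotQAError, ValueError):
    """A data value violates a type invariant (e.g. negative LOT)."""


class FormatError(LotQAError, ValueError):
    """A file is structurally malformed (bad header, duplicate rows...)."""


class ShapeMismatchError(LotQAError, ValueError):
    """Planned and measured sinograms do not share a shape."""


class UndefinedStatisticError(LotQAError, ArithmeticError):
    """The requested statistic is undefined for the given input
    (empty plan, constant correlation input, zero-variance t-test)."""


class InsufficientDataError(LotQAError, ValueError):
    """Too few observations for the requested procedure."""


class ConfigurationError(LotQAError, ValueError):
    """A required column or configuration entry is missing."""
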