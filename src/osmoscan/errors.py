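"""Exception hierarchy for the osmoscan package.

CLI exit-code mapping: FormatError -> 2, ParameterError and its
subclasses -> 3, everything else propagates as an ordinary failure.
"""


class OsmoscanError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OsmoscanError, ValueError):
    """A parameter or configuration value violates its invariants."""


class ConstructionError(OsmoscanError):
    """A synthetic curve segment could not be built monotonically."""


class TooFewPointsError(OsmoscanError):
    """Fewer than the minimum number of curve points survive preprocessing."""


class FormatError(OsmoscanError):
    """A file could not be parsed; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(OsmoscanError, KeyError):
    """A required table column is missing."""


class InsufficientDataError(OsmoscanError):
    """Too few observations for the requested statistical test."""


class CollinearityError(OsmoscanError):
    """Design matrix is rank deficient; names the offending columns."""


class MeasurementError(OsmoscanError, ValueError):
    """A physical measurement is out of its valid domain (e.g. dry >= wet)."""


class PairingError(OsmoscanError):
    """Samples could not be paired across fractions or donors."""


class PackingError(OsmoscanError):
    """Synthetic mask generation could not place all requested cells."""
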