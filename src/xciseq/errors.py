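"""Exception hierarchy for the xciseq pipeline."""


class XciseqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(XciseqError):
    """Invalid user-supplied configuration (bad fractions, thresholds, sizes)."""


class DataError(XciseqError):
    """Inconsistent or malformed data (chromosome mismatches, conflicting records)."""


class CoordinateError(DataError):
    """A genomic coordinate falls outside its chromosome."""


class ParseError(DataError):
    """A record in an input file could not be parsed."""
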