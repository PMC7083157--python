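"""Exception types raised across the package."""


class PhenoanomalyError(ValueError):
    """Base class for domain errors."""


class CatchDataError(PhenoanomalyError):
    """Invalid, duplicate or un-imputable daily catch data."""


class ClimateDataError(PhenoanomalyError):
    """Malformed climate files or incomplete seasonal windows."""


class AnalysisError(PhenoanomalyError):
    """Statistical preconditions not met (rank, sample size, variance)."""
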