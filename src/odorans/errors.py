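"""Exception hierarchy for the odorans pipeline.

Every error raised on a *data* pathway derives from :class:`DataError`, and
every error caused by an invalid parameterisation derives from
:class:`ConfigurationError`, so the CLI can map the two families onto its
exit codes (1 = configuration, 2 = data).
"""


class OdoransError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OdoransError):
    """Invalid parameter value or inconsistent configuration."""


class DataError(OdoransError):
    """The input data cannot support the requested computation."""


class UnusableRecordError(DataError):
    """Flat, saturated or otherwise unprocessable raw signal."""


class UnreliableSeriesError(DataError):
    """Too large a fraction of beat intervals needed correction."""


class InsufficientDataError(DataError):
    """Fewer usable samples/intervals than the estimator requires."""


class WindowTooShortError(DataError):
    """Analysis window shorter than the estimator's minimum span."""


class DegenerateSampleError(DataError):
    """Constant sample where a spread-dependent statistic was requested."""


class NoInformationError(DataError):
    """All paired differences are zero; the test carries no information."""


class DataQualityError(DataError):
    """Signal violates physical plausibility (e.g. strongly negative skin conductance)."""
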