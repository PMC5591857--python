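"""Exception hierarchy for songmem.

All errors raised on invalid user input derive from :class:`SongmemError`
(itself a ``ValueError``) so callers can catch one type at the pipeline
boundary while tests can assert on the specific subclass.
"""


class SongmemError(ValueError):
    """Base class for all songmem validation and analysis errors."""


class ConfigurationError(SongmemError):
    """A configuration field violates its invariant; names the field."""


class EpochWindowError(SongmemError):
    """A stimulus/baseline window is empty, overlapping, or outside the epoch."""


class SeriesValidationError(SongmemError):
    """A response series has missing or duplicated trials."""


class UndefinedRateError(SongmemError):
    """Adaptation rate undefined (window mean magnitude at or below epsilon)."""


class MissingNovelRatesError(SongmemError):
    """A site x test-set group has no novel-stimulus rates to average."""


class EmptyCellError(SongmemError):
    """A requested pooling or reference cell contains no usable records."""


class DegenerateInputError(SongmemError):
    """A statistical test received degenerate input (all ties, zero variance, empty sample)."""


class MissingHousekeepingError(SongmemError):
    """A qPCR sample lacks its housekeeping-gene CT measurement."""
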