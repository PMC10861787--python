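"""Exception hierarchy for MR analyses.

All package errors derive from :class:`MRError` so callers (notably the
pipeline, which degrades failed legs to "not estimable" rather than aborting)
can catch one base class.
"""


class MRError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MRError):
    """Input file does not match the expected delimited-text layout."""


class EmptyInputError(MRError):
    """An input contained no usable rows."""


class EmptyInstrumentError(MRError):
    """No SNP passed the instrument significance threshold."""


class EmptyHarmonizationError(MRError):
    """No SNP survived allele harmonization."""


class InsufficientInstrumentsError(MRError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(MRError):
    """Instrument with a zero exposure effect cannot form a Wald ratio."""


class CollinearityError(MRError):
    """Rank-deficient exposure matrix in multivariable MR."""


class ConfigurationError(MRError):
    """A parameter value is outside its allowed range."""


class UndefinedProportionError(MRError):
    """Mediated proportion is undefined (zero total effect)."""
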