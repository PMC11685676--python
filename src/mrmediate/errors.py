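"""Exception hierarchy for the MR mediation pipeline.

Every failure mode a caller may want to catch programmatically gets its own
class; all inherit from :class:`MRError` so blanket handling stays possible.
"""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """A run/option configuration is invalid (e.g. a missing column mapping)."""


class MissingColumnError(ConfigurationError):
    """A required summary-statistics column is absent from the input file."""


class EmptyInputError(MRError):
    """An input table or file contains no usable rows."""


class HarmonizationError(MRError):
    """No SNP survived exposure/outcome allele harmonization."""


class InsufficientInstrumentsError(MRError):
    """An estimator was handed fewer SNPs than its minimum."""


class NoInstrumentsError(MRError):
    """Instrument selection emptied the candidate set.

    ``stage`` names the selection stage that removed the last SNP.
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class UndefinedRatioError(MRError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class UndefinedProportionError(MRError):
    """Mediated proportion requested with a total effect below the floor."""
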