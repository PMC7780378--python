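"""Exception hierarchy shared across the pipeline."""


class PdListenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PdListenError):
    """A configuration value is inconsistent with the loaded lexicons."""


class LexiconFormatError(PdListenError):
    """A lexicon file violates the required schema."""


class UndefinedGrowthError(PdListenError):
    """CAGR requested with a zero starting value."""


class UndefinedDenominatorError(PdListenError):
    """Share of voice requested for a year with no included dialogues."""
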