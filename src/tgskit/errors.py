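"""Exception hierarchy for tgskit.

All user-facing failures derive from :class:`TgskitError` so callers (and the
command-line wrapper) can distinguish bad inputs from programming errors.
"""


class TgskitError(Exception):
    """Base class for all tgskit errors."""


class PanelValidationError(TgskitError):
    """A SNP panel file or entry violates the panel schema."""


class GenotypeParseError(TgskitError):
    """A genotype input (VCF or TSV) is malformed."""


class ConfigurationError(TgskitError):
    """Inputs are individually valid but mutually inconsistent."""


class UndefinedStatisticError(TgskitError):
    """A statistic is undefined for the given data (e.g. zero typed calls)."""


class DegenerateGroupError(TgskitError):
    """A group is too small (or otherwise degenerate) for the requested test."""
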