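"""Exception hierarchy shared across the toolkit."""


class CatscreenError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CatscreenError):
    """A SMILES or structure record could not be parsed.

    Carries the offending input string in ``args[0]``.
    """


class DegenerateMoleculeError(CatscreenError):
    """Standardization left no usable structure (e.g. a bare counter-ion)."""


class EmptyLibraryError(CatscreenError):
    """An operation that needs at least one molecule received none."""


class ConfigurationError(CatscreenError):
    """An invalid option value (unknown format, bad fraction, k <= 0 ...)."""


class ValidationError(CatscreenError):
    """Input data violates a documented precondition (non-positive activity,
    single-class training set ...)."""


class UndefinedMetricError(CatscreenError):
    """A statistic has a zero denominator or a single-class input; the
    message names the metric."""


class ContractError(CatscreenError):
    """Feature blocks or dimensions do not line up between components."""


class StratificationError(CatscreenError):
    """A cross-validation fold would not contain both classes."""


class CapacityError(CatscreenError):
    """The fragment grammar cannot yield the requested number of unique
    molecules."""
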