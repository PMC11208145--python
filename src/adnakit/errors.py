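"""Exception hierarchy shared across the package."""


class AdnakitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AdnakitError, ValueError):
    """A numeric or categorical parameter is outside its valid domain."""


class PedigreeError(AdnakitError, ValueError):
    """Pedigree graph is malformed (cycle, unknown parent, duplicate label)."""


class FormatError(AdnakitError, ValueError):
    """An input file violates its format contract (dimension mismatch etc.)."""


class DegenerateCohortError(AdnakitError, ValueError):
    """A cohort-level statistic is undefined (e.g. zero background PMR)."""


class DegenerateTableError(AdnakitError, ValueError):
    """A contingency table is too degenerate for the requested statistic."""


class UndefinedRateError(AdnakitError, ValueError):
    """A coverage rate is undefined (zero autosomal coverage)."""
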