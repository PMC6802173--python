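"""Exception hierarchy shared across the pipeline."""


class SeregnetError(Exception):
    """Base class for all package-specific errors."""


class PeakParseError(SeregnetError):
    """A peak or annotation file line could not be parsed; carries the line number."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class FormatError(SeregnetError):
    """Structurally valid file lacking a required column or field."""


class ConfigurationError(SeregnetError):
    """Invalid parameter combination or missing configuration entry."""


class CapacityError(SeregnetError):
    """Synthetic placement cannot fit the requested entities into the genome."""


class EmptyInputError(SeregnetError):
    """An operation that requires at least one record received none."""


class InsufficientDataError(SeregnetError):
    """Too few records to carry out the computation (e.g. < 3 regions to rank)."""


class DegenerateCurveError(SeregnetError):
    """Rank-signal curve has zero signal range; no elbow exists."""


class DegenerateProfilesError(SeregnetError):
    """All expression profiles are identical; clustering cannot separate classes."""

    def __init__(self, genes):
        self.genes = list(genes)
        shown = ", ".join(self.genes[:10])
        more = "" if len(self.genes) <= 10 else f" (+{len(self.genes) - 10} more)"
        super().__init__(f"identical profiles for all genes: {shown}{more}")


class UnassignableError(SeregnetError):
    """No gene available on a peak's chromosome for target assignment."""


class NormalizationError(SeregnetError):
    """Depth normalization impossible (zero total reads)."""
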