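"""Exception hierarchy shared across the package."""


class RIError(Exception):
    """Base class for all package-specific errors."""


class UndefinedBarrierError(RIError):
    """A barrier statistic is undefined (zero denominator)."""


class InvalidCountError(RIError, ValueError):
    """A count or proportion input is negative or otherwise out of range."""


class UndefinedIndexError(RIError):
    """Bateman's constancy index is undefined (all transition counts zero)."""


class InvalidComponentError(RIError, ValueError):
    """A cascade component value lies outside [0, 1]."""


class SchemaError(RIError, ValueError):
    """Input records violate the documented file or record schema."""


class UndefinedFstError(RIError):
    """Per-locus FST is undefined (monomorphic in both samples or no calls)."""


class EmptyPanelError(RIError):
    """No diagnostic loci were found; class assignment refuses to run."""
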