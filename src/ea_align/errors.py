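"""Exception hierarchy for ea_align.

All domain errors derive from :class:`EaAlignError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class EaAlignError(Exception):
    """Base class for all ea_align domain errors."""


class InvalidCurveError(EaAlignError, ValueError):
    """A rating curve or SRVF violates its invariants."""


class InvalidWarpError(EaAlignError, ValueError):
    """A warping function is not a valid element of the warping group."""


class IllConditionedWarpError(EaAlignError, ValueError):
    """A warping function cannot be inverted reliably (flat segment)."""


class InvalidConfigError(EaAlignError, ValueError):
    """An alignment or simulation configuration is inconsistent."""


class CannotSmoothError(EaAlignError, ValueError):
    """A raw rating series has too few distinct time points to smooth."""


class UndefinedCorrelationError(EaAlignError, ValueError):
    """A Pearson correlation is undefined (zero-variance input)."""


class GenerationError(EaAlignError, RuntimeError):
    """A synthetic-data generator failed repeatedly (diagnostic)."""


class DataFormatError(EaAlignError, ValueError):
    """An input file does not follow the documented CSV dialect."""
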