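"""Exception hierarchy for grsmr.

Everything raised on bad user input derives from :class:`GrsmrError`, itself a
``ValueError``, so callers can catch one type.
"""


class GrsmrError(ValueError):
    """Base class for all grsmr errors."""


class SchemaError(GrsmrError):
    """A table is missing a required column or violates a column invariant."""


class TableParseError(GrsmrError):
    """A cell could not be parsed; the message names the offending row."""


class EmptyInstrumentError(GrsmrError):
    """No instrument SNPs survived harmonization (or none were supplied)."""


class DegenerateInstrumentError(GrsmrError):
    """All instrument weights are zero; the causal slope is unidentified."""


class InsufficientMarkersError(GrsmrError):
    """Fewer markers than the operation needs (heterogeneity needs >= 2)."""


class EmptyScoreError(GrsmrError):
    """No SNP passed the polygenic-score p-value threshold."""


class DegenerateScoreError(GrsmrError):
    """The raw polygenic score has zero variance and cannot be standardized."""


class FitError(GrsmrError):
    """A regression fit failed (separation, non-convergence, single class)."""
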