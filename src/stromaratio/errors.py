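"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`StromaRatioError`, so batch drivers
can catch one base class and record a per-slide skip reason instead of
aborting a whole run.
"""


class StromaRatioError(Exception):
    """Base class for all package errors."""


class ParameterError(StromaRatioError):
    """A parameter is outside its admissible range."""


class SizeError(StromaRatioError):
    """A requested geometry does not fit inside the image."""


class ContractError(StromaRatioError):
    """A pluggable component violated its interface contract."""


class DataError(StromaRatioError):
    """Input data violates the schema or basic sanity constraints."""


class EmptyMapError(StromaRatioError):
    """A class map contains no usable (non-NODATA) pixels."""


class NoValidFovError(StromaRatioError):
    """No candidate field of view satisfies the tissue-fraction rule."""


class NoTumorError(StromaRatioError):
    """The class map contains no tumor pixels."""


class EmptyRomError(StromaRatioError):
    """Thresholding produced an empty region of measurement."""


class EmptyTissueError(StromaRatioError):
    """A region of measurement contains no tumor or stroma pixels."""


class ConsensusRequiredError(StromaRatioError):
    """Two raters disagree and no third score was supplied."""


class DegenerateInputError(StromaRatioError):
    """A statistic is undefined on the given input (e.g. constant series)."""


class NoAdmissibleCutoffError(StromaRatioError):
    """No cutoff in the search grid produces two usable groups."""


class FitError(StromaRatioError):
    """A model fit failed to converge or is undefined (e.g. no events)."""


class SpecError(StromaRatioError):
    """A synthetic-data specification is unattainable."""
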