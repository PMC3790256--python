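"""Exception hierarchy for pnmkit.

Every error raised by the library derives from :class:`PnmError` so callers
(and the CLI) can catch one type at the pipeline boundary.
"""


class PnmError(Exception):
    """Base class for all pnmkit errors."""


class FormatError(PnmError):
    """A physiological log or design file does not match its declared layout."""


class TimingError(PnmError):
    """Sample or trigger timing is inconsistent beyond tolerance."""


class PeakDetectionError(PnmError):
    """Cardiac/respiratory peak detection failed (degenerate or too few peaks)."""


class DegenerateSignalError(PnmError):
    """A trace is constant / all-NaN, so phases or rates cannot be derived."""


class DOFError(PnmError):
    """Effective degrees of freedom would be non-positive."""


class NestingError(PnmError):
    """Model-comparison inputs violate the nesting requirements."""


class DimensionError(PnmError):
    """Array shapes of data, designs or masks do not line up."""


class RankError(PnmError):
    """A design matrix is rank deficient; message names the collinear columns."""


class SummaryError(PnmError):
    """A mask summary was requested over an empty or all-undefined region."""
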