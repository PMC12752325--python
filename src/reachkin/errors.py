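"""Exception hierarchy for reachkin."""


class ReachkinError(Exception):
    """Base class for all reachkin errors."""


class FormatError(ReachkinError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(ReachkinError, ValueError):
    """Input values violate a documented invariant."""


class EmptySeriesError(ReachkinError):
    """An operation received a landmark series or track with no frames."""


class InsufficientFramesError(ReachkinError):
    """An operation needs at least two frames (speeds are inter-frame)."""


class UnsupportedConfigurationError(ReachkinError):
    """A closed-form oracle was requested for a configuration it does not cover."""


class RankDeficientDesignError(ReachkinError):
    """The fixed-effects design matrix is rank deficient.

    Carries the names of the collinear columns in ``columns``.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient fixed-effects design; collinear columns: "
            + ", ".join(self.columns)
        )
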