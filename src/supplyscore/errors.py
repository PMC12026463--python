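"""Exception hierarchy shared across the scoring modules."""


class SupplyScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(SupplyScoreError):
    """Invalid input data or configuration; the message names the offending field."""


class MissingIndicator(SupplyScoreError):
    """Raised by an indicator sub-assessment when it has no data to work with.

    The aggregation layer catches this and treats the indicator as absent,
    redistributing its weight over the remaining indicators rather than
    scoring it as zero.
    """

    def __init__(self, indicator: str, detail: str = ""):
        self.indicator = indicator
        msg = f"{indicator} indicator missing"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
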