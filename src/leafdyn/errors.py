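"""Exception and warning types shared across the pipeline.

Batch drivers catch :class:`LeafDynError` subclasses and record a missing
observation with a machine-readable reason code instead of aborting.
"""


class LeafDynError(Exception):
    """Base class for all leafdyn-specific errors."""


class NoLeafFound(LeafDynError):
    """Segmentation produced no connected component above the minimum area."""


class ZeroAreaError(LeafDynError):
    """A measurement was requested on an empty pixel region."""


class InvariantViolation(LeafDynError):
    """A domain invariant was broken (e.g. etiolated area exceeding leaf area)."""


class AchromaticError(LeafDynError):
    """Hue is undefined: the colour is too close to gray (saturation < 0.05)."""


class DivisionByZero(LeafDynError):
    """Colour indices requested for an all-zero RGB triple."""


class MissingObservation(LeafDynError):
    """The observation does not exist (e.g. a senesced leaf); not a failure.

    Carries a short machine-readable ``reason`` string.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class NonPositiveValue(LeafDynError):
    """Relative growth rate requested for a non-positive characteristic value."""


class BadInterval(LeafDynError):
    """A rate was requested over a non-increasing time interval (t2 <= t1)."""


class BadSpacing(LeafDynError):
    """The requested period spacing is not representable on the schedule."""


class FitFailure(LeafDynError):
    """Nonlinear least squares failed to converge from every starting point."""


class DegenerateLabels(LeafDynError):
    """Classifier training requested with fewer than two classes present."""


class EmptyDataset(LeafDynError):
    """No modelling rows survive after dropping rows with missing cells."""


class TipAmbiguous(UserWarning):
    """Leaf mask too round to orient reliably; tip chosen by fixed convention."""
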