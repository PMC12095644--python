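"""Exception hierarchy for pipeline failures.

Every stage failure raises a subclass of :class:`FlowsegError` carrying the
stage name, so batch drivers can isolate per-image failures and report the
stage that broke.
"""


class FlowsegError(Exception):
    """Base class for all pipeline errors."""

    stage = "unknown"


class DegenerateInputError(FlowsegError):
    """Image has no dynamic range (max == min): nothing to segment."""

    stage = "normalize"


class ImageReadError(FlowsegError):
    """File missing, unreadable, or an invalid channel was requested."""

    stage = "read"


class ContractError(FlowsegError):
    """Inputs violate an operation precondition (e.g. shape mismatch)."""

    stage = "contract"


class SelfTuningError(FlowsegError):
    """Threshold self-tuning failed: every candidate left a class empty."""

    stage = "self_label"


class LabelingError(FlowsegError):
    """Thresholds produced an empty cell or background class."""

    stage = "self_label"


class TrainingError(FlowsegError):
    """Too few self-labeled pixels in a class to train the classifier."""

    stage = "classify"


class GenerationError(FlowsegError):
    """Synthetic fixture generation could not satisfy its constraints."""

    stage = "synth"
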