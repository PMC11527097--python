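"""Exception types shared across the package."""


class SguqError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(SguqError):
    """Sample IDs do not line up across modalities / labels / splits."""


class ParseError(SguqError):
    """A data file contains a non-numeric or non-finite cell."""


class ZeroNormSampleError(SguqError):
    """A sample's feature vector has zero norm; cosine similarity is undefined."""


class DegenerateLabelsError(SguqError):
    """The training set contains a single class; cross-entropy fit is degenerate."""


class TrainingDivergedError(SguqError):
    """A training loss became non-finite."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class EnsembleTrialError(SguqError):
    """One trial of an ensemble failed; carries the trial index."""

    def __init__(self, message: str, trial: int):
        super().__init__(message)
        self.trial = trial
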