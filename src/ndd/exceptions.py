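"""Exception hierarchy shared by all pipeline stages."""


class NDDError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(NDDError):
    """A matrix has the wrong shape for the drug index or its partner."""


class FormatError(NDDError):
    """A file or array contains values outside the allowed domain."""


class IdentifierError(NDDError):
    """Drug identifiers in a file do not match the run's drug index."""


class ConsistencyError(NDDError):
    """An interaction matrix is asymmetric or otherwise self-contradictory."""


class DegenerateInputError(NDDError):
    """An input is valid in shape but carries no usable signal (e.g. all-zero)."""


class SelectionEmptyError(NDDError):
    """The entropy filter removed every candidate similarity view."""


class ParameterError(NDDError):
    """A configuration value is outside its legal range."""


class TrainingDataError(NDDError):
    """The training set cannot support fitting (e.g. a single class)."""


class MetricUndefinedError(NDDError):
    """A ranking metric was requested on single-class labels."""
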