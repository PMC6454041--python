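"""Exception hierarchy shared across the pipeline stages."""


class N2AError(Exception):
    """Base class for all package errors."""


class InputError(N2AError):
    """A required input file is missing or unreadable."""


class ParseError(N2AError):
    """An input file is present but malformed; message names the location."""


class ValidationError(N2AError):
    """Data violates a documented contract (weights, dimensions, set sizes...)."""


class ConvergenceError(N2AError):
    """An iterative solver exhausted its iteration budget."""


class TrainingError(N2AError):
    """Model training diverged (non-finite loss)."""


class UndefinedMetricError(N2AError):
    """A metric is undefined on the given input (e.g. single-class AUROC)."""
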