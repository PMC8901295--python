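"""Exception hierarchy for dtfnet.

All dtfnet-specific failures derive from :class:`DtfnetError` so callers
(notably the CLI) can distinguish pipeline failures from programming errors.
"""


class DtfnetError(Exception):
    """Base class for all dtfnet errors."""


class ValidationError(DtfnetError, ValueError):
    """Input data violates a container invariant (shape, labels, finiteness)."""


class MontageError(DtfnetError, ValueError):
    """A requested channel label is absent from the trial set."""


class EstimationError(DtfnetError, RuntimeError):
    """A model fit failed (too little data, rank deficiency, degenerate input)."""


class OrderSelectionError(DtfnetError, RuntimeError):
    """AIC order selection could not evaluate any candidate order."""


class SingularSpectrumError(DtfnetError, RuntimeError):
    """The MVAR characteristic matrix A(f) is numerically singular at some f."""


class StabilityError(DtfnetError, ValueError):
    """An MVAR model is unstable (companion spectral radius >= 1)."""


class ProtocolError(DtfnetError, ValueError):
    """An evaluation scheme cannot be realised on the given data."""


class ConfigError(DtfnetError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
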