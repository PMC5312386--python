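"""Exception and warning types shared across the pipeline."""


class WntpipeError(Exception):
    """Base class for all pipeline errors."""


class InputError(WntpipeError):
    """Malformed or inconsistent input data."""


class DegenerateLayoutError(WntpipeError):
    """Plate layout leaves no usable sample wells for the spatial fit."""


class ZeroSpreadError(WntpipeError):
    """A scale estimate is exactly zero, so standardization is undefined."""


class ZeroScaleError(WntpipeError):
    """Robust scale estimation attempted on identical values."""


class NonConvergenceError(WntpipeError):
    """Iterative estimator failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class CoverageError(WntpipeError):
    """Signature genes missing from the expression matrix."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class NoCutoffError(WntpipeError):
    """No valid expression cutoff exists (e.g. constant expression)."""


class UnstableScaleWarning(UserWarning):
    """Scale estimated from fewer values than recommended."""


class EmptyResultWarning(UserWarning):
    """An operation produced an empty result (e.g. disjoint gene sets)."""
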