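"""Exception types raised across the package."""


class KansurvError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KansurvError, ValueError):
    """Malformed configuration (knot vectors, simulation parameters, ...)."""


class ShapeError(KansurvError, ValueError):
    """Input width does not match the model's expected number of features."""


class UnseenCategoryError(KansurvError, KeyError):
    """A categorical lookup received a level code never seen during training."""


class UndefinedLossError(KansurvError, ValueError):
    """The Cox partial likelihood is undefined (no observed events)."""


class UndefinedCIndexError(KansurvError, ValueError):
    """No admissible pairs exist, so the concordance index is undefined."""


class ConvergenceError(KansurvError, RuntimeError):
    """An optimizer failed to reach its tolerance.

    Carries the final gradient (or proximal-residual) norm in
    ``final_gradient_norm``.
    """

    def __init__(self, message: str, final_gradient_norm: float | None = None):
        super().__init__(message)
        self.final_gradient_norm = final_gradient_norm


class AllPrunedError(KansurvError, ValueError):
    """Pruning removed every path to the output node."""


class DivergenceError(KansurvError, RuntimeError):
    """Training produced a non-finite loss. Carries the offending step."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
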