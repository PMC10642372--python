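"""Exception hierarchy.

All package errors derive from :class:`CaeriskError` so callers can catch
broadly; the subclasses distinguish bad parameters, bad data, bad
configuration, and model-fitting failures.
"""


class CaeriskError(Exception):
    """Base class for all package errors."""


class ParameterError(CaeriskError, ValueError):
    """A function argument is outside its valid domain."""


class DataError(CaeriskError, ValueError):
    """Input data violate a structural precondition."""


class ConfigError(CaeriskError, ValueError):
    """A configuration file or design definition is inconsistent."""


class ConvergenceError(CaeriskError, RuntimeError):
    """An iterative fit failed to converge."""


class SeparationError(ConvergenceError):
    """Complete separation: the conditional-logistic MLE is infinite.

    ``covariate`` names the offending column.
    """

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"complete separation detected for covariate {covariate!r}: "
            "the odds-ratio estimate diverges"
        )
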