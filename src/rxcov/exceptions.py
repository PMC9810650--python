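"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`RxcovError`
so that the CLI can convert any failure into a structured message instead
of a traceback.
"""


class RxcovError(Exception):
    """Base class for all rxcov errors."""


class ValidationError(RxcovError):
    """Malformed or out-of-contract input data."""


class InsufficientDataError(ValidationError):
    """Too few observations to compute the requested statistic."""


class PairingError(ValidationError):
    """Vectors that must be sample-aligned have incompatible lengths."""


class DomainError(RxcovError):
    """Argument outside the mathematical domain of a function."""


class DegenerateStatisticError(DomainError):
    """One of the four summary statistics feeding the metric is not
    strictly positive.

    Attributes
    ----------
    statistic : str
        Which of ``mu_z``, ``mu_n``, ``sigma_z``, ``sigma_n`` failed.
    """

    def __init__(self, statistic: str, value: float):
        self.statistic = statistic
        self.value = value
        super().__init__(
            f"degenerate input: {statistic} = {value!r} must be strictly positive"
        )


class ConfigError(RxcovError):
    """Invalid simulation or CLI configuration."""
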