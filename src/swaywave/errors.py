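"""Exception hierarchy shared by all swaywave modules."""


class SwayWaveError(Exception):
    """Base class for all swaywave errors."""


class ValidationError(SwayWaveError, ValueError):
    """Input data failed validation (bad file, non-finite sample, out-of-range value)."""


class ParameterError(SwayWaveError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff >= Nyquist, k < 1)."""


class ZeroEnergyError(SwayWaveError, ArithmeticError):
    """Relative energy is undefined because the decomposition carries no energy."""


class RankDeficientError(SwayWaveError, ValueError):
    """The regression design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class SwayWaveWarning(UserWarning):
    """Non-fatal condition (e.g. wavelet scale exceeding half the record length)."""
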