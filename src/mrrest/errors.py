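"""Exception hierarchy shared across the package."""


class MrrestError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MrrestError, ValueError):
    """An input violated a documented invariant; the message names the rule."""


class ParseError(MrrestError, ValueError):
    """A file could not be parsed; the message names the offending row."""


class ExtrapolationError(MrrestError, ValueError):
    """An age outside a rate table's span was requested (no silent extrapolation)."""


class SingularityError(MrrestError, ArithmeticError):
    """A denominator in a closed-form identity vanished."""


class NonIdentifiableError(MrrestError, ValueError):
    """se + sp <= 1: the misclassification correction is not identifiable."""


class InfeasibleCorrectionError(MrrestError, ValueError):
    """A corrected proportion fell outside [0, 1].

    Carries the raw (unclipped) value in ``raw_value`` so callers can inspect
    how far outside the feasible range the correction landed.
    """

    def __init__(self, raw_value: float, what: str = "corrected value"):
        self.raw_value = raw_value
        super().__init__(
            f"{what} {raw_value!r} lies outside [0, 1]; "
            "the observed data are inconsistent with the supplied accuracy"
        )


class IntegrationError(MrrestError, RuntimeError):
    """The prevalence solver left the admissible range [0, 1)."""
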