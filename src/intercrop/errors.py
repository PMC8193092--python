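"""Exception hierarchy shared across the package."""


class IntercropError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IntercropError):
    """Invalid configuration value (unknown noise model, bad design, ...)."""


class ValidationError(IntercropError):
    """Input data failed schema validation.

    ``problems`` lists one human-readable message per offending row/column.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("\n".join(self.problems))


class InsufficientDataError(IntercropError):
    """Too few observations to attempt an operation."""


class NonIdentifiableError(IntercropError):
    """The data carry no growth signal (constant / all-zero series)."""


class MissingTruthError(IntercropError):
    """A synthetic design requests a (species, context, response) with no truth."""


class CalibrationError(IntercropError):
    """A week with isotope data has no beta calibration entry."""


class ReferencePlantError(IntercropError):
    """No non-legume delta15N available at a week x diversity level."""
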