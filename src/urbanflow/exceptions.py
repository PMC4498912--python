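"""Exception hierarchy for urbanflow."""


class UrbanFlowError(Exception):
    """Base class for all urbanflow errors."""


class ConfigurationError(UrbanFlowError):
    """Invalid configuration or parameter values.

    Carries an optional list of individual problems in ``problems``.
    """

    def __init__(self, message, problems=None):
        super().__init__(message)
        self.problems = list(problems) if problems else []


class GenerationError(UrbanFlowError):
    """Population or environment generation cannot proceed."""


class SelectionError(UrbanFlowError):
    """No valid destination can be selected."""


class IntegrityError(UrbanFlowError):
    """A data structure violates one of its invariants."""


class AnalysisError(UrbanFlowError):
    """An analysis operation received degenerate or inconsistent input."""
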