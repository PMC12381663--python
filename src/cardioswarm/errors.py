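"""Exception types shared across the package."""


class CardioSwarmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioSwarmError):
    """Invalid model name, parameter vector, protocol or run configuration."""


class DegenerateDataError(CardioSwarmError):
    """Data that cannot be normalized or compared (e.g. constant input)."""


class GenerationError(CardioSwarmError):
    """Synthetic-data generation failed (e.g. the model never excites)."""
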