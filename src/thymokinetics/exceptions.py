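"""Exception hierarchy."""


class ThymoKineticsError(Exception):
    """Base class for all package errors."""


class ValidationError(ThymoKineticsError, ValueError):
    """Invalid parameters, states, designs or configuration."""


class SteadyStateError(ThymoKineticsError):
    """No finite steady state exists for the requested parameters."""


class IdentifiabilityError(ThymoKineticsError):
    """The requested free parameters cannot be identified from the data design."""
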