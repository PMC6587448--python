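"""Exception types used across the toolkit."""


class PanforgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PanforgeError):
    """A simulation or analysis configuration is internally contradictory."""


class InputError(PanforgeError):
    """Input data violates a documented precondition."""
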