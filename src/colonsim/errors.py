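"""Exception hierarchy used across the package."""


class ColonsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ColonsimError, ValueError):
    """A structurally invalid model configuration (missing keys, bad counts)."""


class ValidationError(ColonsimError, ValueError):
    """A parameter value that violates a physical or stoichiometric invariant."""


class NumericalError(ColonsimError, RuntimeError):
    """Integration failure or non-finite state encountered at run time."""
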