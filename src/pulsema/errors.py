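"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input violates a physical or mathematical precondition."""


class ConfigurationError(ValueError):
    """A scenario or model configuration is internally inconsistent."""


class DetectionError(RuntimeError):
    """Cycle/onset detection failed on the supplied series."""
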