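"""Exception types shared across pipeline stages."""


class ConfigurationError(ValueError):
    """A config object or code-list file is invalid or incomplete."""


class ValidationError(ValueError):
    """Input data violate a schema or domain invariant."""
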