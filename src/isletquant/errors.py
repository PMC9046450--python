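"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is missing, malformed or out of range."""


class DataError(ValueError):
    """Input data violate a contract (missing label, shape mismatch, ...)."""
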