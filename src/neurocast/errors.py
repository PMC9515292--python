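"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration (rates, proportions, missing models...)."""


class DataError(ValueError):
    """Input data violate a precondition (empty class, empty split...)."""
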