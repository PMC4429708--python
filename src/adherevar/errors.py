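"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (probabilities not summing to 1, missing inputs, ...)."""


class DataError(ValueError):
    """Malformed input data (duplicate patient-months, NaNs, bad posterior rows, ...)."""
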