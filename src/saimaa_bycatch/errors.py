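"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input configuration violates its documented invariants."""


class EstimationError(RuntimeError):
    """A model fit or projection cannot be carried out on the given data."""
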