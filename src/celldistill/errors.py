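class ConfigurationError(ValueError):
    """Invalid configuration (shapes, probabilities, divisibility, ...)."""


class PlacementError(RuntimeError):
    """Requested cells cannot be placed without overlap."""


class IndexingError(ValueError):
    """Duplicate or inconsistent identifiers in an index table."""
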