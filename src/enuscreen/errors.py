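"""Exception types shared across the package."""


class ParameterError(ValueError):
    """Invalid configuration or function parameters."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class GenerationError(RuntimeError):
    """The synthetic-screen generator could not satisfy a request."""
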