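"""Package exception types."""


class EstrocycleError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EstrocycleError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(EstrocycleError, ValueError):
    """Malformed or inconsistent data passed to an analysis operation."""
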