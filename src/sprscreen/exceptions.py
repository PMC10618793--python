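"""Exception hierarchy for sprscreen."""


class SprScreenError(Exception):
    """Base class for all sprscreen errors."""


class FormatError(SprScreenError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(SprScreenError, ValueError):
    """Data violate a structural invariant (e.g. non-monotone time)."""


class ConfigurationError(SprScreenError, ValueError):
    """A required configuration item is missing or inconsistent."""


class FitError(SprScreenError, RuntimeError):
    """A least-squares fit is degenerate or failed to converge."""
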