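"""Package-specific error types."""


class ShankvbError(Exception):
    """Base class for all shankvb errors."""


class ValidationError(ShankvbError, ValueError):
    """A specification or argument violates a documented precondition."""


class PackingError(ShankvbError, RuntimeError):
    """Bundle placement failed: the requested bundles do not fit."""


class EmptySectionError(ShankvbError, ValueError):
    """No foreground tissue found when segmenting a section image."""


class ZoneConsistencyError(ShankvbError, ValueError):
    """A bundle lies outside the section it is being assigned within."""
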