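"""Exception hierarchy shared across the package."""


class TeleacuityError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TeleacuityError, ValueError):
    """An argument is outside the physically or logically valid domain."""


class UndisplayableError(TeleacuityError):
    """Not even a single crowded letter fits the presentation window."""


class ProtocolError(TeleacuityError):
    """An observer failed to produce a usable response."""


class ScriptExhaustedError(ProtocolError):
    """A scripted observer ran out of pre-recorded responses mid-test."""


class InsufficientDataError(TeleacuityError, ValueError):
    """Too few paired measurements to compute the requested statistic."""
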