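"""Exception hierarchy shared across the package."""


class CytoloopError(Exception):
    """Base class for all package errors."""


class ChannelError(CytoloopError):
    """A required cytometry channel is absent after channel-name mapping."""


class FormatError(CytoloopError):
    """The FCS file declares a dialect outside the supported subset."""


class IntegrityError(CytoloopError):
    """The file or stream is internally inconsistent (e.g. truncated data)."""


class ValidationError(CytoloopError):
    """Input values violate a precondition (non-finite intensity, bad config)."""


class OrderingError(CytoloopError):
    """Timestamps are not strictly increasing."""


class ConsistencyError(CytoloopError):
    """Paired inputs disagree in length or identity."""


class ActuatorAlarm(CytoloopError):
    """The pump actuator failed to acknowledge a command after retry."""
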