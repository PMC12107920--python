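"""Exception hierarchy.

Errors are split along the lines the retry policy cares about: anything
raised while handling a queued analysis request counts as a failed attempt,
whereas :class:`Hl7Error` subclasses raised during order intake map onto the
acknowledgment codes (AE for unparseable input, AR for profile violations).
"""


class HistolinkError(Exception):
    """Base class for all package errors."""


class Hl7Error(HistolinkError):
    """Base class for HL7 message errors."""


class Hl7ParseError(Hl7Error):
    """Input bytes/text could not be parsed as an HL7 v2 message."""


class Hl7StructureError(Hl7Error):
    """A required segment or field is missing from a message."""


class ProfileViolationError(Hl7Error):
    """Message parses but violates the integration profile (e.g. two SPM)."""


class ValidationError(HistolinkError):
    """Invalid payload or domain object."""


class MllpProtocolError(Hl7Error):
    """Bytes received outside an MLLP frame."""


class ConfigError(HistolinkError):
    """Invalid registry or server configuration."""


class ResolutionError(HistolinkError):
    """A model name does not resolve in the registry."""


class ContractError(HistolinkError):
    """Backend output does not match the model spec's contract."""


class SlideIOError(HistolinkError):
    """A slide could not be located or read (a retryable failure)."""


class DeliveryError(HistolinkError):
    """Result delivery failed (timeout, refused connection, or ACK != AA)."""


class DataError(HistolinkError):
    """Inconsistent coordinate or table data (e.g. negative offset result)."""
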