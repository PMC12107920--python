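"""Generic HL7 v2 segment/field model with pipe-and-hat encoding.

Only the subset of the standard needed by the integration profile is
modelled: segments, 1-based fields, 1-based components, and the escape
sequences for the default encoding characters ``| ^ ~ \\ &``. Repetitions
and subcomponents are not used by the profile and are treated as opaque
text inside a component.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from histolink.errors import Hl7ParseError, Hl7StructureError, ValidationError

#: Default HL7 encoding characters: field, component, repetition, escape,
#: subcomponent. The profile fixes these; MSH-1/MSH-2 advertise them.
ENCODING_CHARS = "|^~\\&"

FIELD_SEP = "|"
COMPONENT_SEP = "^"
REPETITION_SEP = "~"
ESCAPE_CHAR = "\\"
SUBCOMPONENT_SEP = "&"

SEGMENT_SEP = "\r"

HL7_VERSION = "2.6"

# Escape sequences per the standard: \F\ field sep, \S\ component sep,
# \T\ subcomponent sep, \R\ repetition sep, \E\ escape char.
_ESCAPES = [
    (ESCAPE_CHAR, "\\E\\"),  # must be first on escape, last on unescape
    (FIELD_SEP, "\\F\\"),
    (COMPONENT_SEP, "\\S\\"),
    (SUBCOMPONENT_SEP, "\\T\\"),
    (REPETITION_SEP, "\\R\\"),
]


def escape_text(value: str) -> str:
    """Escape HL7 delimiter characters in a user-supplied string."""
    for char, seq in _ESCAPES:
        value = value.replace(char, seq)
    return value


def unescape_text(value: str) -> str:
    """Inverse of :func:`escape_text`."""
    for char, seq in reversed(_ESCAPES):
        value = value.replace(seq, char)
    return value


@dataclass
class Segment:
    """One HL7 segment: a 3-letter name plus ordered fields.

    Fields are stored unescaped; each field is a list of components.
    Addressing is 1-based to match HL7 convention, so ``seg.component(4, 2)``
    is the value written ``XXX.4.2`` in interface specifications.
    """

    name: str
    fields: list[list[str]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.name) != 3 or not self.name.isalnum():
            raise ValidationError(f"invalid segment name: {self.name!r}")
        self.name = self.name.upper()

    # -- accessors ---------------------------------------------------------

    def field(self, n: int) -> str:
        """Field ``n`` (1-based) as a component-joined string."""
        comps = self._components(n)
        return COMPONENT_SEP.join(comps)

    def component(self, n: int, m: int) -> str:
        """Component ``m`` of field ``n`` (both 1-based); '' when absent."""
        comps = self._components(n)
        return comps[m - 1] if 0 < m <= len(comps) else ""

    def _components(self, n: int) -> list[str]:
        if n < 1:
            raise IndexError("HL7 field numbers are 1-based")
        if n > len(self.fields):
            return []
        return self.fields[n - 1]

    def set_field(self, n: int, *components: str) -> None:
        """Set field ``n`` (1-based), padding intermediate fields with ''."""
        while len(self.fields) < n:
            self.fields.append([""])
        self.fields[n - 1] = [str(c) for c in components] or [""]

    # -- wire format -------------------------------------------------------

    def encode(self) -> str:
        if self.name == "MSH":
            # MSH-1 is the field separator itself and MSH-2 the encoding
            # characters; neither is escaped.
            rest = [
                COMPONENT_SEP.join(escape_text(c) for c in f)
                for f in self.fields[2:]
            ]
            return FIELD_SEP.join(["MSH", ENCODING_CHARS[1:], *rest])
        encoded = [
            COMPONENT_SEP.join(escape_text(c) for c in f) for f in self.fields
        ]
        return FIELD_SEP.join([self.name, *encoded])

    @classmethod
    def decode(cls, raw: str) -> "Segment":
        if len(raw) < 3:
            raise Hl7ParseError(f"segment too short: {raw!r}")
        name = raw[:3]
        if name == "MSH":
            if len(raw) < 8 or raw[3] != FIELD_SEP:
                raise Hl7ParseError("malformed MSH segment")
            body = raw[4:].split(FIELD_SEP)
            # body[0] is MSH-2 (encoding characters), kept verbatim.
            fields: list[list[str]] = [[FIELD_SEP], [body[0]]]
            for f in body[1:]:
                fields.append([unescape_text(c) for c in f.split(COMPONENT_SEP)])
            return cls("MSH", fields)
        parts = raw.split(FIELD_SEP)
        if parts[0] != name:
            raise Hl7ParseError(f"malformed segment: {raw!r}")
        fields = [
            [unescape_text(c) for c in f.split(COMPONENT_SEP)] for f in parts[1:]
        ]
        return cls(name, fields)


@dataclass
class Hl7Message:
    """An ordered list of segments beginning with MSH."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments or self.segments[0].name != "MSH":
            raise ValidationError("HL7 message must begin with MSH")

    # -- MSH convenience ---------------------------------------------------

    @property
    def msh(self) -> Segment:
        return self.segments[0]

    @property
    def message_type(self) -> str:
        """Message code and trigger event, e.g. ``OML^O33`` or ``ACK``."""
        code = self.msh.component(9, 1)
        trigger = self.msh.component(9, 2)
        return f"{code}^{trigger}" if trigger else code

    @property
    def control_id(self) -> str:
        return self.msh.field(10)

    @property
    def version(self) -> str:
        return self.msh.field(12)

    # -- segment access ----------------------------------------------------

    def segments_named(self, name: str) -> list[Segment]:
        return [s for s in self.segments if s.name == name.upper()]

    def segment(self, name: str) -> Segment:
        """The unique segment ``name``; raises if absent."""
        found = self.segments_named(name)
        if not found:
            raise Hl7StructureError(f"missing {name.upper()} segment")
        return found[0]

    # -- wire format -------------------------------------------------------

    def encode(self) -> str:
        return SEGMENT_SEP.join(s.encode() for s in self.segments) + SEGMENT_SEP

    def to_bytes(self) -> bytes:
        return self.encode().encode("utf-8")

    @classmethod
    def decode(cls, text: str) -> "Hl7Message":
        # Tolerate \n or \r\n segment terminators from hand-edited fixtures.
        normalized = text.replace("\r\n", "\r").replace("\n", "\r")
        lines = [ln for ln in normalized.split(SEGMENT_SEP) if ln]
        if not lines:
            raise Hl7ParseError("empty message")
        segments = [Segment.decode(ln) for ln in lines]
        if segments[0].name != "MSH":
            raise Hl7ParseError("message does not begin with MSH")
        return cls(segments)

    @classmethod
    def from_bytes(cls, data: bytes) -> "Hl7Message":
        try:
            text = data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise Hl7ParseError(f"message is not valid UTF-8: {exc}") from exc
        return cls.decode(text)


def build_msh(
    message_type: str,
    control_id: str,
    *,
    sending_app: str = "AI-DSS",
    sending_facility: str = "HISTOLINK",
    receiving_app: str = "AP-LIS",
    receiving_facility: str = "LAB",
    timestamp: str = "",
) -> Segment:
    """Build an MSH segment for the profile (HL7 v2.6, processing id P)."""
    if not control_id:
        raise ValidationError("control_id must be non-empty")
    msh = Segment("MSH", [[FIELD_SEP], [ENCODING_CHARS[1:]]])
    msh.set_field(3, sending_app)
    msh.set_field(4, sending_facility)
    msh.set_field(5, receiving_app)
    msh.set_field(6, receiving_facility)
    msh.set_field(7, timestamp)
    msh.set_field(8, "")
    msh.set_field(9, *message_type.split(COMPONENT_SEP))
    msh.set_field(10, control_id)
    msh.set_field(11, "P")
    msh.set_field(12, HL7_VERSION)
    return msh
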