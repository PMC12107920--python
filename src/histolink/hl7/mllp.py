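"""Minimal Lower Layer Protocol byte framing.

MLLP wraps each HL7 message as ``0x0B <payload> 0x1C 0x0D`` on a TCP
stream. :class:`MllpBuffer` incrementally splits a stream into complete
message payloads, buffering partial frames across ``feed`` calls.
"""

from __future__ import annotations

from histolink.errors import MllpProtocolError

START_BLOCK = b"\x0b"
END_BLOCK = b"\x1c\x0d"


def mllp_frame(payload: bytes) -> bytes:
    """Wrap one HL7 message's bytes in an MLLP frame."""
    return START_BLOCK + payload + END_BLOCK


class MllpBuffer:
    """Incremental MLLP de-framer for a byte stream."""

    def __init__(self) -> None:
        self._buffer = b""

    def feed(self, data: bytes) -> list[bytes]:
        """Consume bytes; return the payloads of any completed frames.

        Raises :class:`MllpProtocolError` on bytes that appear outside a
        frame (the stream must be a concatenation of frames).
        """
        self._buffer += data
        messages: list[bytes] = []
        while self._buffer:
            if not self._buffer.startswith(START_BLOCK):
                raise MllpProtocolError(
                    f"bytes outside MLLP frame: {self._buffer[:16]!r}"
                )
            end = self._buffer.find(END_BLOCK)
            if end == -1:
                break  # partial frame: wait for more bytes
            messages.append(self._buffer[1:end])
            self._buffer = self._buffer[end + len(END_BLOCK):]
        return messages

    @property
    def pending(self) -> bool:
        """True when a partial frame is buffered."""
        return bool(self._buffer)


def mllp_unframe(data: bytes) -> list[bytes]:
    """Split a complete byte string into framed message payloads.

    Raises :class:`MllpProtocolError` if the data does not end on a frame
    boundary or contains bytes outside frames.
    """
    buffer = MllpBuffer()
    messages = buffer.feed(data)
    if buffer.pending:
        raise MllpProtocolError("trailing partial MLLP frame")
    return messages
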