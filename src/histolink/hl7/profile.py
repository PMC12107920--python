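"""The three-message integration profile: OML^O33, ACK, OUL^R21.

Profile conventions
-------------------
* Every ``OML^O33`` orders analysis of a single whole-slide image with a
  single model, hence exactly one SPM segment and one ORC/OBR pair.
* The model is carried in ``SPM.4.1`` (code) and ``SPM.4.2`` (name); the
  slide's filesystem location in ``OBR.13``. ``OBR.11`` distinguishes the
  two order modes: ``A`` (automatic, default mode) vs ``O`` (on-demand).
* Results go back as OBX segments in an ``OUL^R21``: the first OBX is
  always the model name (ST); binary artifacts are Base64 in ED segments;
  slide-level labels/scores are ST/NM pairs.
"""

from __future__ import annotations

import base64
import binascii
import datetime as _dt
import itertools
import threading
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Union

from histolink.errors import (
    Hl7StructureError,
    ProfileViolationError,
    ValidationError,
)
from histolink.hl7.message import Hl7Message, Segment, build_msh

if TYPE_CHECKING:  # pragma: no cover
    from histolink.inference import InferenceBundle
    from histolink.registry import ModelSpec

ACK_CODES = ("AA", "AE", "AR")

#: OBX-3 identifiers used by the profile.
OBX_MODEL_NAME = "MODEL_NAME"
OBX_TISSUE_MASK = "TISSUE_MASK"
OBX_TILE_PREDICTIONS = "TILE_PREDICTIONS"
OBX_RUN_METADATA = "RUN_METADATA"
OBX_TOP_TILE = "TOP_TILE_{i}"
OBX_SLIDE_LABEL = "SLIDE_LABEL"
OBX_SLIDE_SCORE = "SLIDE_SCORE"
OBX_RISK_CLASS = "RISK_CLASS"
OBX_RISK_SCORE = "RISK_SCORE"


def _now() -> str:
    return _dt.datetime.now().strftime("%Y%m%d%H%M%S")


class ControlIdGenerator:
    """Monotonically increasing message control IDs with a fixed prefix."""

    def __init__(self, prefix: str = "HLK") -> None:
        self._prefix = prefix
        self._counter = itertools.count(1)
        self._lock = threading.Lock()

    def __call__(self) -> str:
        with self._lock:
            return f"{self._prefix}{next(self._counter):06d}"


_default_ids = ControlIdGenerator()


@dataclass(frozen=True)
class OrderPayload:
    """The content of one analysis order: one slide, one model."""

    model_code: str
    model_name: str
    wsi_location: str
    patient_id: str = ""
    slide_id: str = ""

    def validate(self) -> None:
        if not self.model_name:
            raise ValidationError("EMPTY_MODEL_NAME: model_name is required")
        if not self.wsi_location:
            raise ValidationError("EMPTY_WSI_LOCATION: wsi_location is required")


@dataclass
class ObxPayload:
    """One observation: ST/NM text or an ED Base64 binary artifact."""

    set_id: int
    value_type: str  # ST | NM | ED
    identifier: str
    value: Union[str, bytes]
    subtype: str = ""  # ED data subtype, e.g. JPEG / CSV / JSON

    def __post_init__(self) -> None:
        if self.set_id < 1:
            raise ValidationError("OBX set_id must be a positive integer")
        if self.value_type not in ("ST", "NM", "ED"):
            raise ValidationError(f"unsupported OBX value type {self.value_type}")
        if self.value_type == "ED" and not isinstance(self.value, bytes):
            raise ValidationError("ED payloads must be bytes")
        if self.value_type != "ED" and isinstance(self.value, bytes):
            raise ValidationError("text payloads must be str")

    def to_segment(self) -> Segment:
        seg = Segment("OBX")
        seg.set_field(1, str(self.set_id))
        seg.set_field(2, self.value_type)
        seg.set_field(3, self.identifier)
        seg.set_field(4, "")
        if self.value_type == "ED":
            b64 = base64.b64encode(self.value).decode("ascii")
            seg.set_field(5, "", "application", self.subtype, "Base64", b64)
        else:
            seg.set_field(5, str(self.value))
        seg.set_field(11, "F")  # final result
        return seg

    @classmethod
    def from_segment(cls, seg: Segment) -> "ObxPayload":
        if seg.name != "OBX":
            raise Hl7StructureError(f"expected OBX, got {seg.name}")
        try:
            set_id = int(seg.field(1))
        except ValueError as exc:
            raise Hl7StructureError(f"bad OBX set id {seg.field(1)!r}") from exc
        value_type = seg.field(2)
        identifier = seg.component(3, 1)
        if value_type == "ED":
            encoding = seg.component(5, 4)
            if encoding != "Base64":
                raise Hl7StructureError(f"unsupported ED encoding {encoding!r}")
            try:
                raw = base64.b64decode(seg.component(5, 5), validate=True)
            except (binascii.Error, ValueError) as exc:
                raise ValidationError(f"corrupt Base64 in OBX {set_id}") from exc
            return cls(set_id, "ED", identifier, raw, seg.component(5, 3))
        return cls(set_id, value_type, identifier, seg.field(5))


# ---------------------------------------------------------------------------
# OML^O33 — order message


def build_oml_o33(
    payload: OrderPayload,
    *,
    mode: str = "on_demand",
    control_id: Optional[str] = None,
    timestamp: Optional[str] = None,
) -> Hl7Message:
    """Build a laboratory order message for one slide and one model."""
    payload.validate()
    if mode not in ("default", "on_demand"):
        raise ValidationError(f"unknown order mode {mode!r}")
    msh = build_msh(
        "OML^O33^OML_O33",
        control_id or _default_ids(),
        sending_app="AP-LIS",
        receiving_app="AI-DSS",
        timestamp=timestamp if timestamp is not None else _now(),
    )
    pid = Segment("PID")
    pid.set_field(3, payload.patient_id)
    spm = Segment("SPM")
    spm.set_field(1, "1")
    spm.set_field(2, payload.slide_id)
    spm.set_field(4, payload.model_code, payload.model_name)
    orc = Segment("ORC")
    orc.set_field(1, "NW")  # new order
    obr = Segment("OBR")
    obr.set_field(1, "1")
    obr.set_field(11, "A" if mode == "default" else "O")
    obr.set_field(13, payload.wsi_location)
    return Hl7Message([msh, pid, spm, orc, obr])


def parse_oml_o33(message: Hl7Message) -> OrderPayload:
    """Extract the order payload; enforces the single-SPM/ORC-OBR profile."""
    if message.message_type.split("^")[0:2] != ["OML", "O33"]:
        raise ProfileViolationError(
            f"expected OML^O33, got {message.message_type}"
        )
    for name in ("SPM", "ORC", "OBR"):
        count = len(message.segments_named(name))
        if count == 0:
            raise Hl7StructureError(f"missing {name} segment")
        if count > 1:
            raise ProfileViolationError(
                f"profile requires exactly one {name} segment, found {count}"
            )
    spm = message.segment("SPM")
    obr = message.segment("OBR")
    pid_segments = message.segments_named("PID")
    payload = OrderPayload(
        model_code=spm.component(4, 1),
        model_name=spm.component(4, 2),
        wsi_location=obr.field(13),
        patient_id=pid_segments[0].field(3) if pid_segments else "",
        slide_id=spm.field(2),
    )
    payload.validate()
    return payload


def parse_order_mode(message: Hl7Message) -> str:
    """Order mode from OBR.11: 'default' (A) or 'on_demand' (O, default)."""
    return "default" if message.segment("OBR").field(11) == "A" else "on_demand"


# ---------------------------------------------------------------------------
# ACK


def build_ack(
    original: Hl7Message,
    code: str,
    *,
    control_id: Optional[str] = None,
    timestamp: Optional[str] = None,
) -> Hl7Message:
    """Acknowledge ``original`` with MSA-1 = code, MSA-2 = its control id."""
    if code not in ACK_CODES:
        raise ValidationError(f"unknown ACK code {code!r}")
    if original.message_type.split("^")[0] == "ACK":
        raise ProfileViolationError("refusing to acknowledge an ACK")
    if not original.control_id:
        raise ValidationError("original message has no control id")
    msh = build_msh(
        "ACK",
        control_id or _default_ids(),
        timestamp=timestamp if timestamp is not None else _now(),
    )
    msa = Segment("MSA")
    msa.set_field(1, code)
    msa.set_field(2, original.control_id)
    return Hl7Message([msh, msa])


def ack_code(ack: Hl7Message) -> str:
    """MSA-1 of an ACK message."""
    return ack.segment("MSA").field(1)


# ---------------------------------------------------------------------------
# OUL^R21 — result message


def build_oul_r21(
    bundle: "InferenceBundle",
    spec: "ModelSpec",
    *,
    control_id: Optional[str] = None,
    timestamp: Optional[str] = None,
    patient_id: str = "",
) -> Hl7Message:
    """Package an inference bundle as an unsolicited observation message.

    OBX layout by task kind:

    * always: OBX#1 = ST model name;
    * patch-level models: + 3 ED segments (tissue-mask JPEG,
      tile-prediction CSV, run-metadata JSON), Base64;
    * binary patch-level models: + up to 5 ED segments with the
      top-scoring tile JPEGs;
    * slide-level models: + ST predicted label / risk class and
      NM prediction / risk score.
    """
    if bundle.spec_name != spec.name:
        raise ValidationError(
            f"bundle built for {bundle.spec_name!r}, spec is {spec.name!r}"
        )
    bundle.validate(spec)

    payloads: list[ObxPayload] = [ObxPayload(1, "ST", OBX_MODEL_NAME, spec.name)]
    next_id = itertools.count(2)

    if spec.task_kind in ("patch_binary", "patch_multiclass"):
        payloads.append(
            ObxPayload(next(next_id), "ED", OBX_TISSUE_MASK,
                       bundle.mask_jpeg, "JPEG")
        )
        payloads.append(
            ObxPayload(next(next_id), "ED", OBX_TILE_PREDICTIONS,
                       bundle.tile_csv_bytes(), "CSV")
        )
        payloads.append(
            ObxPayload(next(next_id), "ED", OBX_RUN_METADATA,
                       bundle.metadata_json_bytes(), "JSON")
        )
        if spec.task_kind == "patch_binary":
            for i, tile in enumerate(bundle.top_tiles, start=1):
                payloads.append(
                    ObxPayload(next(next_id), "ED",
                               OBX_TOP_TILE.format(i=i), tile, "JPEG")
                )
    else:  # slide-level
        label_id = (OBX_RISK_CLASS if spec.task_kind == "slide_mil_survival"
                    else OBX_SLIDE_LABEL)
        score_id = (OBX_RISK_SCORE if spec.task_kind == "slide_mil_survival"
                    else OBX_SLIDE_SCORE)
        payloads.append(
            ObxPayload(next(next_id), "ST", label_id, str(bundle.slide_label))
        )
        payloads.append(
            ObxPayload(next(next_id), "NM", score_id,
                       format(bundle.slide_score, "g"))
        )

    msh = build_msh(
        "OUL^R21^OUL_R21",
        control_id or _default_ids(),
        timestamp=timestamp if timestamp is not None else _now(),
    )
    pid = Segment("PID")
    pid.set_field(3, patient_id)
    segments = [msh, pid] + [p.to_segment() for p in payloads]
    return Hl7Message(segments)


@dataclass
class OulSummary:
    """Decoded view of an OUL^R21, as the LIS side would consume it."""

    model_name: str
    artifacts: dict[str, bytes]
    slide_label: Optional[str]
    slide_score: Optional[float]
    payloads: list[ObxPayload]

    @property
    def top_tiles(self) -> list[bytes]:
        keys = sorted(k for k in self.artifacts if k.startswith("TOP_TILE_"))
        return [self.artifacts[k] for k in keys]


def parse_obx_segments(message: Hl7Message) -> list[ObxPayload]:
    """All OBX segments as payloads, validating the 1..N set-id sequence."""
    payloads = [
        ObxPayload.from_segment(s) for s in message.segments_named("OBX")
    ]
    ids = [p.set_id for p in payloads]
    if ids != list(range(1, len(ids) + 1)):
        raise Hl7StructureError(f"OBX set ids not sequential from 1: {ids}")
    return payloads


def parse_oul_r21(message: Hl7Message) -> OulSummary:
    """Decode a result message back into its artifacts and summary values."""
    if message.message_type.split("^")[0:2] != ["OUL", "R21"]:
        raise ProfileViolationError(
            f"expected OUL^R21, got {message.message_type}"
        )
    payloads = parse_obx_segments(message)
    if not payloads:
        raise Hl7StructureError("OUL^R21 carries no OBX segments")
    first = payloads[0]
    if first.identifier != OBX_MODEL_NAME or first.value_type != "ST":
        raise Hl7StructureError("OBX#1 must be the ST model name")

    artifacts: dict[str, bytes] = {}
    slide_label: Optional[str] = None
    slide_score: Optional[float] = None
    for p in payloads[1:]:
        if p.value_type == "ED":
            artifacts[p.identifier] = p.value  # type: ignore[assignment]
        elif p.identifier in (OBX_SLIDE_LABEL, OBX_RISK_CLASS):
            slide_label = str(p.value)
        elif p.identifier in (OBX_SLIDE_SCORE, OBX_RISK_SCORE):
            slide_score = float(p.value)
    return OulSummary(str(first.value), artifacts, slide_label, slide_score,
                      payloads)
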