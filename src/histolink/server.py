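"""The decision-support runtime: order intake, FIFO queue, retry, delivery.

The service plays two roles. In *server* mode it listens for order
messages, acknowledges each one immediately (before any processing) and
appends it to a FIFO queue. A single sequential worker consumes the
queue — one inference at a time, so completion order of successful
requests equals arrival order — while listening continues concurrently.
For each dispatched request the worker resolves the model, runs
inference, builds the heatmap project, then switches to *client* mode:
it transmits the result message to the LIS endpoint and waits for the
acknowledgment, after which the connection is closed.

Any raised error in those stages, including delivery failures and a
negative acknowledgment from the LIS, counts as a failed attempt. A
request is dispatched at most three times (re-entering at the queue
head, with no backoff); after the third failure it is marked failed and
the next queued slide proceeds, so one bad slide never blocks the rest.

Two timing counters are recorded per request: the total time from order
arrival to the final LIS acknowledgment, and the inference-plus-project
time alone.
"""

from __future__ import annotations

import collections
import logging
import socket
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from histolink.errors import (
    DeliveryError,
    Hl7Error,
    ProfileViolationError,
    ValidationError,
)
from histolink.hl7.message import Hl7Message, Segment, build_msh
from histolink.hl7.mllp import MllpBuffer, mllp_frame
from histolink.hl7.profile import (
    ControlIdGenerator,
    OrderPayload,
    ack_code,
    build_ack,
    build_oul_r21,
    parse_oml_o33,
    parse_order_mode,
)
from histolink.registry import ModelSpec, Registry

log = logging.getLogger("histolink.server")

MAX_ATTEMPTS = 3
DEFAULT_ACK_TIMEOUT = 30.0


@dataclass
class AnalysisRequest:
    """One queued slide-model analysis with its retry state."""

    order: OrderPayload
    mode: str = "on_demand"
    enqueued_at: float = 0.0
    attempts: int = 0
    status: str = "queued"  # queued | running | succeeded | failed

    def __post_init__(self) -> None:
        if self.mode not in ("default", "on_demand"):
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass
class TimingRecord:
    """The two per-request counters (seconds)."""

    total_request_seconds: float
    inference_and_project_seconds: float


@dataclass
class CompletedRequest:
    request: AnalysisRequest
    timing: Optional[TimingRecord] = None
    error: Optional[str] = None


#: processor(request, spec) -> (InferenceBundle, HeatmapProject)
Processor = Callable[[AnalysisRequest, ModelSpec], tuple]
#: result_sender(message, request) -> ACK message from the LIS
ResultSender = Callable[[Hl7Message, AnalysisRequest], Hl7Message]


def default_mode_trigger(
    registry: Registry,
    wsi_location: str,
    tissue_type: str,
    staining: str,
    *,
    patient_id: str = "",
    slide_id: str = "",
    now: float = 0.0,
) -> list[AnalysisRequest]:
    """Requests triggered automatically when a slide is digitized.

    One request per model registered for the slide's (tissue type,
    staining) combination; an empty list (no match) is logged, not an
    error.
    """
    specs = registry.lookup_default(tissue_type, staining)
    if not specs:
        log.info(
            "no default-mode models for (%s, %s)", tissue_type, staining
        )
    return [
        AnalysisRequest(
            order=OrderPayload(
                model_code=spec.name,
                model_name=spec.name,
                wsi_location=str(wsi_location),
                patient_id=patient_id,
                slide_id=slide_id,
            ),
            mode="default",
            enqueued_at=now,
        )
        for spec in specs
    ]


def _error_ack(code: str, original_control_id: str = "",
               ids: Optional[ControlIdGenerator] = None) -> Hl7Message:
    """ACK for a message whose original could not be (fully) parsed."""
    msh = build_msh("ACK", (ids or ControlIdGenerator("ERR"))())
    msa = Segment("MSA")
    msa.set_field(1, code)
    msa.set_field(2, original_control_id)
    return Hl7Message([msh, msa])


class AiDssCore:
    """Queue, retry policy, and per-request processing, transport-free.

    The socket layer feeds raw order bytes in and supplies a
    ``result_sender``; tests can drive the core directly with scripted
    processors and senders.
    """

    def __init__(
        self,
        registry: Registry,
        processor: Optional[Processor] = None,
        result_sender: Optional[ResultSender] = None,
        *,
        max_attempts: int = MAX_ATTEMPTS,
        seed: int = 0,
        project_root: Optional[Path] = None,
        clock: Callable[[], float] = time.monotonic,
        control_ids: Optional[ControlIdGenerator] = None,
        fixed_timestamp: Optional[str] = None,
    ) -> None:
        self.registry = registry
        self.processor = processor or self._default_processor
        self.result_sender = result_sender or self._no_sender
        self.max_attempts = max_attempts
        self.seed = seed
        self.project_root = Path(project_root) if project_root else None
        self.clock = clock
        self.control_ids = control_ids or ControlIdGenerator("DSS")
        # injectable MSH-7 for reproducible wire transcripts
        self.fixed_timestamp = fixed_timestamp
        self._queue: collections.deque[AnalysisRequest] = collections.deque()
        self._lock = threading.Lock()
        self.history: list[CompletedRequest] = []

    # -- intake ------------------------------------------------------------

    def handle_order_bytes(
        self, raw: bytes
    ) -> tuple[Hl7Message, Optional[AnalysisRequest]]:
        """Parse an incoming order; return (ACK, enqueued request or None).

        AA on success, AE when the bytes do not parse, AR on a profile
        violation (e.g. two SPM segments). Nothing is enqueued unless
        the ACK is AA.
        """
        try:
            message = Hl7Message.from_bytes(raw)
        except Hl7Error:
            return _error_ack("AE", ids=self.control_ids), None
        try:
            payload = parse_oml_o33(message)
            mode = parse_order_mode(message)
        except ProfileViolationError:
            return _error_ack("AR", message.control_id, self.control_ids), None
        except (Hl7Error, ValidationError):
            return _error_ack("AE", message.control_id, self.control_ids), None
        request = AnalysisRequest(
            order=payload, mode=mode, enqueued_at=self.clock()
        )
        self.enqueue(request)
        return build_ack(message, "AA", control_id=self.control_ids()), request

    def enqueue(self, request: AnalysisRequest) -> None:
        with self._lock:
            self._queue.append(request)

    def requeue_at_head(self, request: AnalysisRequest) -> None:
        with self._lock:
            self._queue.appendleft(request)

    @property
    def pending(self) -> int:
        with self._lock:
            return len(self._queue)

    # -- processing --------------------------------------------------------

    def _default_processor(self, request: AnalysisRequest, spec: ModelSpec):
        from histolink.pipeline import process_order

        project_dir = None
        if self.project_root is not None:
            stem = Path(request.order.wsi_location).stem or "slide"
            project_dir = self.project_root / f"{stem}__{spec.name}"
        return process_order(
            request.order.wsi_location, spec,
            seed=self.seed, project_dir=project_dir,
        )

    def _no_sender(self, message: Hl7Message,
                   request: AnalysisRequest) -> Hl7Message:
        raise DeliveryError("no result sender configured")

    def process_next(self) -> Optional[AnalysisRequest]:
        """Dispatch the queue head once; returns it, or None if idle.

        On success the request is marked succeeded and its timing
        recorded; on any failure the attempt counter decides between
        re-enqueueing at the head and marking the request failed.
        """
        with self._lock:
            if not self._queue:
                return None
            request = self._queue.popleft()
        request.status = "running"
        request.attempts += 1
        try:
            spec = self.registry.resolve(request.order.model_name)
            t_inf0 = self.clock()
            bundle, project = self.processor(request, spec)
            t_inf1 = self.clock()
            oul = build_oul_r21(
                bundle, spec,
                control_id=self.control_ids(),
                timestamp=self.fixed_timestamp,
                patient_id=request.order.patient_id,
            )
            ack = self.result_sender(oul, request)
            code = ack_code(ack)
            if code != "AA":
                raise DeliveryError(f"LIS acknowledged with {code}")
            done = self.clock()
            request.status = "succeeded"
            self.history.append(
                CompletedRequest(
                    request,
                    TimingRecord(
                        total_request_seconds=done - request.enqueued_at,
                        inference_and_project_seconds=t_inf1 - t_inf0,
                    ),
                )
            )
        except Exception as exc:  # any stage failure counts as an attempt
            log.warning(
                "attempt %d/%d for %s failed: %s",
                request.attempts, self.max_attempts,
                request.order.model_name, exc,
            )
            if request.attempts >= self.max_attempts:
                request.status = "failed"
                self.history.append(CompletedRequest(request, error=str(exc)))
            else:
                request.status = "queued"
                self.requeue_at_head(request)
        return request

    def drain(self) -> None:
        """Process until the queue is empty (including retries)."""
        while self.process_next() is not None:
            pass


# ---------------------------------------------------------------------------
# Transport


def send_result(
    message: Hl7Message,
    endpoint: tuple[str, int],
    timeout: float = DEFAULT_ACK_TIMEOUT,
) -> Hl7Message:
    """Client mode: transmit a result message, wait for the ACK, close.

    Raises :class:`DeliveryError` on connection failure or when no
    complete ACK arrives within the timeout.
    """
    try:
        with socket.create_connection(endpoint, timeout=timeout) as conn:
            conn.sendall(mllp_frame(message.to_bytes()))
            buffer = MllpBuffer()
            deadline = time.monotonic() + timeout
            while True:
                remaining = deadline - time.monotonic()
                if remaining <= 0:
                    raise DeliveryError("timed out waiting for ACK")
                conn.settimeout(remaining)
                chunk = conn.recv(4096)
                if not chunk:
                    raise DeliveryError("connection closed before ACK")
                frames = buffer.feed(chunk)
                if frames:
                    return Hl7Message.from_bytes(frames[0])
    except (OSError, Hl7Error) as exc:
        raise DeliveryError(f"result delivery failed: {exc}") from exc


class AiDssServer:
    """MLLP/TCP front end around :class:`AiDssCore`.

    Listens for orders (acknowledging and enqueueing each immediately)
    while a single worker thread consumes the queue and delivers
    results to the configured LIS endpoint.
    """

    def __init__(
        self,
        core: AiDssCore,
        *,
        host: str = "127.0.0.1",
        port: int = 0,
        ap_lis_endpoint: Optional[tuple[str, int]] = None,
        ack_timeout: float = DEFAULT_ACK_TIMEOUT,
    ) -> None:
        self.core = core
        self.host = host
        self.port = port
        self.ack_timeout = ack_timeout
        if ap_lis_endpoint is not None:
            core.result_sender = (
                lambda msg, req: send_result(msg, ap_lis_endpoint, ack_timeout)
            )
        self._listener: Optional[socket.socket] = None
        self._threads: list[threading.Thread] = []
        self._stop = threading.Event()

    @property
    def endpoint(self) -> tuple[str, int]:
        if self._listener is None:
            raise RuntimeError("server not started")
        return self._listener.getsockname()[:2]

    def start(self) -> None:
        self._listener = socket.create_server((self.host, self.port))
        self._listener.settimeout(0.2)
        accept = threading.Thread(target=self._accept_loop, daemon=True)
        worker = threading.Thread(target=self._worker_loop, daemon=True)
        self._threads = [accept, worker]
        accept.start()
        worker.start()

    def stop(self) -> None:
        self._stop.set()
        for t in self._threads:
            t.join(timeout=5)
        if self._listener is not None:
            self._listener.close()
            self._listener = None

    def serve_forever(self) -> None:  # pragma: no cover - CLI entry
        self.start()
        try:
            while not self._stop.is_set():
                time.sleep(0.2)
        except KeyboardInterrupt:
            pass
        finally:
            self.stop()

    # -- internals ---------------------------------------------------------

    def _accept_loop(self) -> None:
        while not self._stop.is_set():
            try:
                conn, _addr = self._listener.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            threading.Thread(
                target=self._handle_connection, args=(conn,), daemon=True
            ).start()

    def _handle_connection(self, conn: socket.socket) -> None:
        buffer = MllpBuffer()
        with conn:
            conn.settimeout(self.ack_timeout)
            while not self._stop.is_set():
                try:
                    chunk = conn.recv(4096)
                except (socket.timeout, OSError):
                    break
                if not chunk:
                    break
                try:
                    frames = buffer.feed(chunk)
                except Hl7Error:
                    conn.sendall(mllp_frame(_error_ack("AE").to_bytes()))
                    break
                for raw in frames:
                    ack, _request = self.core.handle_order_bytes(raw)
                    conn.sendall(mllp_frame(ack.to_bytes()))

    def _worker_loop(self) -> None:
        while not self._stop.is_set():
            if self.core.process_next() is None:
                time.sleep(0.02)
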