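"""Synthetic fixtures: slides, scripted backends, and a mock LIS peer.

Everything needed to exercise the full order-to-overlay loop at desk
scale with no downloads: small tiled-TIFF "slides" with elliptical
tissue blobs on a bright background, deterministic in their seed; a
scripted backend wrapper for exercising the failure/retry path; a mock
LIS that sends orders, accepts result messages, and acknowledges (or
misbehaves) per scenario while recording the full wire transcript; and
an end-to-end driver returning every intermediate artifact.
"""

from __future__ import annotations

import socket
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import tifffile

from histolink.errors import DeliveryError
from histolink.heatmap import import_project
from histolink.hl7.message import Hl7Message
from histolink.hl7.mllp import MllpBuffer, mllp_frame
from histolink.hl7.profile import (
    OrderPayload,
    OulSummary,
    build_ack,
    build_oml_o33,
    parse_oul_r21,
)
from histolink.registry import Registry, load_registry
from histolink.server import AiDssCore, AiDssServer, AnalysisRequest
from histolink.slides import SlideMetadata, SlideReader, open_slide, sidecar_path

FIXED_TIMESTAMP = "20240101120000"


# ---------------------------------------------------------------------------
# Synthetic slides


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Recipe for one synthetic slide; same spec => byte-identical files.

    ``dimensions`` is the size of the imaged region written to the TIFF;
    with a non-zero ``bounds_offset`` the scanner frame is the region
    translated by the offset, as in formats with a non-zero origin.
    """

    seed: int
    dimensions: tuple[int, int] = (2048, 2048)  # (W, H) of the imaged region
    mpp: float = 0.5
    n_blobs: int = 3
    blob_size: tuple[int, int] = (200, 500)  # min/max blob semi-axis span
    bounds_offset: tuple[int, int] = (0, 0)
    tissue_type: str = "colorectal"
    staining: str = "H&E"


def render_slide_image(spec: SyntheticSlideSpec) -> np.ndarray:
    """RGB image of the imaged region: dark eosin-like blobs on glass."""
    rng = np.random.default_rng(spec.seed)
    W, H = spec.dimensions
    image = np.full((H, W, 3), 242, dtype=np.uint8)
    noise = rng.integers(-6, 7, size=(H, W, 1), dtype=np.int16)
    image = np.clip(image.astype(np.int16) + noise, 0, 255).astype(np.uint8)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(spec.n_blobs):
        lo, hi = spec.blob_size
        a = rng.integers(lo // 2, hi // 2 + 1)
        b = rng.integers(lo // 2, hi // 2 + 1)
        cx = rng.integers(a, max(a + 1, W - a))
        cy = rng.integers(b, max(b + 1, H - b))
        blob = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        color = np.array(
            [150 + rng.integers(-20, 21),
             90 + rng.integers(-20, 21),
             130 + rng.integers(-20, 21)],
            dtype=np.uint8,
        )
        image[blob] = color
    return image


def make_slide(
    spec: SyntheticSlideSpec,
    out_dir: Union[str, Path],
    name: str = "slide",
    *,
    mrxs_style: bool = False,
) -> SlideReader:
    """Write a synthetic slide (tiled TIFF + metadata sidecar) and open it.

    With ``mrxs_style`` the slide is written as a container directory
    holding a ``Slidedat.ini`` marker, exercising the directory
    path-resolution convention; otherwise as a plain ``.tif`` file.
    """
    out = Path(out_dir)
    if mrxs_style:
        container = out / f"{name}.mrxs"
        container.mkdir(parents=True, exist_ok=True)
        (container / "Slidedat.ini").write_text(
            "[GENERAL]\nSLIDE_NAME = {}\n".format(name), encoding="utf-8"
        )
        image_path = container / f"{name}.tif"
        location: Path = container
    else:
        out.mkdir(parents=True, exist_ok=True)
        image_path = out / f"{name}.tif"
        location = image_path
    image = render_slide_image(spec)
    tifffile.imwrite(image_path, image, tile=(256, 256), photometric="rgb")
    metadata = SlideMetadata(
        mpp=spec.mpp,
        bounds_offset=spec.bounds_offset,
        tissue_type=spec.tissue_type,
        staining=spec.staining,
        extra={"synthetic": True, "seed": spec.seed},
    )
    sidecar_path(image_path).write_text(metadata.to_json(), encoding="utf-8")
    return open_slide(location, metadata)


# ---------------------------------------------------------------------------
# Scripted backend


@dataclass
class ScriptedBackendPlan:
    """Per-attempt behaviour: 'succeed', 'raise', or ('delay', seconds)."""

    behaviours: list

    def __post_init__(self) -> None:
        for b in self.behaviours:
            if b not in ("succeed", "raise") and not (
                isinstance(b, tuple) and len(b) == 2 and b[0] == "delay"
            ):
                raise ValueError(f"unknown scripted behaviour {b!r}")


class ScriptedBackend:
    """Processor wrapper replaying a plan; replays identically.

    Behaviours are consumed per call; once the plan is exhausted the
    wrapped processor runs unconditionally. ``inner`` may be omitted for
    plans that never succeed.
    """

    def __init__(
        self, plan: ScriptedBackendPlan, inner: Optional[Callable] = None
    ) -> None:
        self.plan = list(plan.behaviours)
        self.inner = inner
        self.calls = 0

    def __call__(self, request, spec):
        self.calls += 1
        behaviour = self.plan.pop(0) if self.plan else "succeed"
        if behaviour == "raise":
            raise RuntimeError("scripted backend failure")
        if isinstance(behaviour, tuple):
            time.sleep(behaviour[1])
        if self.inner is None:
            raise RuntimeError("scripted backend has no inner processor")
        return self.inner(request, spec)


# ---------------------------------------------------------------------------
# Mock LIS peer


@dataclass
class TranscriptEntry:
    direction: str  # sent | received
    message: Hl7Message

    @property
    def message_type(self) -> str:
        return self.message.message_type


class MockApLis:
    """Plays the LIS side: sends orders, receives results, acknowledges.

    ``scenario`` is a list of per-result behaviours ('AA', 'AE' or
    'silent') applied in arrival order; once exhausted, 'AA'. The full
    message transcript is recorded for assertions.
    """

    def __init__(self, scenario: Optional[list[str]] = None) -> None:
        self.scenario = list(scenario or [])
        self.transcript: list[TranscriptEntry] = []
        self.results: list[OulSummary] = []
        self._listener: Optional[socket.socket] = None
        self._thread: Optional[threading.Thread] = None
        self._stop = threading.Event()
        self._lock = threading.Lock()
        self._order_counter = 0

    # -- result listener ---------------------------------------------------

    @property
    def endpoint(self) -> tuple[str, int]:
        if self._listener is None:
            raise RuntimeError("mock LIS not started")
        return self._listener.getsockname()[:2]

    def start(self) -> None:
        self._listener = socket.create_server(("127.0.0.1", 0))
        self._listener.settimeout(0.2)
        self._thread = threading.Thread(target=self._accept_loop, daemon=True)
        self._thread.start()

    def stop(self) -> None:
        self._stop.set()
        if self._thread is not None:
            self._thread.join(timeout=5)
        if self._listener is not None:
            self._listener.close()
            self._listener = None

    def _accept_loop(self) -> None:
        while not self._stop.is_set():
            try:
                conn, _ = self._listener.accept()
            except socket.timeout:
                continue
            except OSError:
                break
            threading.Thread(
                target=self._handle_result, args=(conn,), daemon=True
            ).start()

    def _handle_result(self, conn: socket.socket) -> None:
        buffer = MllpBuffer()
        with conn:
            conn.settimeout(10)
            while not self._stop.is_set():
                try:
                    chunk = conn.recv(4096)
                except (socket.timeout, OSError):
                    return
                if not chunk:
                    return
                for raw in buffer.feed(chunk):
                    message = Hl7Message.from_bytes(raw)
                    with self._lock:
                        behaviour = (
                            self.scenario.pop(0) if self.scenario else "AA"
                        )
                        self.transcript.append(
                            TranscriptEntry("received", message)
                        )
                        if behaviour != "silent":
                            self.results.append(parse_oul_r21(message))
                    if behaviour == "silent":
                        return  # never acknowledge; sender times out
                    ack = build_ack(
                        message, behaviour, timestamp=FIXED_TIMESTAMP
                    )
                    with self._lock:
                        self.transcript.append(TranscriptEntry("sent", ack))
                    conn.sendall(mllp_frame(ack.to_bytes()))
                    return

    # -- order client ------------------------------------------------------

    def send_order(
        self,
        order: OrderPayload,
        endpoint: tuple[str, int],
        *,
        mode: str = "on_demand",
        timeout: float = 10.0,
    ) -> Hl7Message:
        """Transmit one order message and return the service's ACK."""
        with self._lock:
            self._order_counter += 1
            control_id = f"ORD{self._order_counter:04d}"
        message = build_oml_o33(
            order, mode=mode, control_id=control_id, timestamp=FIXED_TIMESTAMP
        )
        with self._lock:
            self.transcript.append(TranscriptEntry("sent", message))
        try:
            with socket.create_connection(endpoint, timeout=timeout) as conn:
                conn.sendall(mllp_frame(message.to_bytes()))
                buffer = MllpBuffer()
                deadline = time.monotonic() + timeout
                while True:
                    remaining = deadline - time.monotonic()
                    if remaining <= 0:
                        raise DeliveryError("no ACK for order")
                    conn.settimeout(remaining)
                    chunk = conn.recv(4096)
                    if not chunk:
                        raise DeliveryError("connection closed before ACK")
                    frames = buffer.feed(chunk)
                    if frames:
                        ack = Hl7Message.from_bytes(frames[0])
                        with self._lock:
                            self.transcript.append(
                                TranscriptEntry("received", ack)
                            )
                        return ack
        except OSError as exc:
            raise DeliveryError(f"order transmission failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Full-loop driver


@dataclass
class LoopResult:
    """Every intermediate artifact of one synthetic end-to-end run."""

    slides: list[SlideReader]
    order_acks: list[Hl7Message]
    results: list[OulSummary]
    transcript: list[TranscriptEntry]
    history: list
    project_dirs: list[Path] = field(default_factory=list)

    @property
    def completed_models(self) -> list[str]:
        return [r.model_name for r in self.results]

    def load_projects(self):
        return [import_project(d) for d in self.project_dirs]


def end_to_end_fixture(
    n_slides: int,
    models: list[str],
    seed: int,
    workdir: Union[str, Path],
    *,
    registry: Optional[Registry] = None,
    scenario: Optional[list[str]] = None,
    timeout: float = 60.0,
) -> LoopResult:
    """Run the full loop over real sockets and collect every artifact.

    Generates ``n_slides`` synthetic slides from ``seed``, sends one
    on-demand order per (slide, model) pair in FIFO order, processes
    them through the queued runtime, and returns messages, summaries
    and exported projects for assertions.
    """
    workdir = Path(workdir)
    registry = registry or load_registry()
    # routine sections fill much of the scanned region, so the loop slides
    # carry dense tissue: every model geometry finds a non-empty grid
    slides = [
        make_slide(
            SyntheticSlideSpec(seed=seed + i, dimensions=(1024, 1024),
                               n_blobs=5, blob_size=(300, 600)),
            workdir / "slides",
            name=f"slide_{i:03d}",
        )
        for i in range(n_slides)
    ]
    lis = MockApLis(scenario=scenario)
    lis.start()
    core = AiDssCore(
        registry,
        seed=seed,
        project_root=workdir / "projects",
        fixed_timestamp=FIXED_TIMESTAMP,
    )
    server = AiDssServer(core, ap_lis_endpoint=lis.endpoint, ack_timeout=5.0)
    server.start()
    n_orders = n_slides * len(models)
    try:
        acks = []
        for reader in slides:
            for model in models:
                order = OrderPayload(
                    model_code=model,
                    model_name=model,
                    wsi_location=reader.ref.path,
                    patient_id="PAT001",
                    slide_id=Path(reader.ref.path).stem,
                )
                acks.append(lis.send_order(order, server.endpoint))
        deadline = time.monotonic() + timeout
        while len(core.history) < n_orders and time.monotonic() < deadline:
            time.sleep(0.05)
    finally:
        server.stop()
        lis.stop()
    project_dirs = sorted((workdir / "projects").glob("*")) \
        if (workdir / "projects").exists() else []
    return LoopResult(
        slides=slides,
        order_acks=acks,
        results=list(lis.results),
        transcript=list(lis.transcript),
        history=list(core.history),
        project_dirs=[p for p in project_dirs if p.is_dir()],
    )
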