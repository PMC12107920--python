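"""Slide access behind a small adapter interface.

The integration is blind to scanner formats: orders carry a filesystem
path, and this module resolves it according to the scanner conventions
(a ``.svs``/``.tif`` file for Leica-style scans, a directory containing
``Slidedat.ini`` for 3DHistech-style ``.mrxs`` containers) and exposes a
uniform reader. Two readers ship: an in-memory synthetic reader and a
tiled-TIFF reader with a JSON metadata sidecar. Some scanner formats
image a sub-region of the glass with a non-zero origin; that origin is
the *bounds offset* and tile coordinates produced here are in the
scanner frame (offset included) — downstream display subtracts it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from histolink.errors import SlideIOError, ValidationError


@dataclass(frozen=True)
class SlideRef:
    """Identity and geometry of one whole-slide image."""

    path: str
    format: str  # mrxs | svs | tiff | synthetic
    mpp: float
    dimensions: tuple[int, int]  # (W, H) in base pixels, scanner frame
    bounds_offset: tuple[int, int] = (0, 0)
    tissue_type: str = ""
    staining: str = ""

    def __post_init__(self) -> None:
        w, h = self.dimensions
        if w <= 0 or h <= 0:
            raise ValidationError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValidationError("mpp must be positive")
        if min(self.bounds_offset) < 0:
            raise ValidationError("bounds offsets must be non-negative")


class SlideReader:
    """Uniform pixel access in the scanner coordinate frame."""

    def __init__(self, ref: SlideRef, image: np.ndarray) -> None:
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValidationError("slide image must be H x W x 3")
        self.ref = ref
        self._image = image

    @property
    def image(self) -> np.ndarray:
        return self._image

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """RGB region at scanner coordinates (clamped to slide bounds)."""
        W, H = self.ref.dimensions
        if w <= 0 or h <= 0:
            raise ValidationError("region size must be positive")
        if not (0 <= x < W and 0 <= y < H):
            raise SlideIOError(f"region origin ({x}, {y}) outside slide")
        return self._image[y:min(y + h, H), x:min(x + w, W)]

    def thumbnail(self, max_edge: int = 512) -> tuple[np.ndarray, float]:
        """Downsampled RGB image and the downsampling factor used."""
        H, W = self._image.shape[:2]
        factor = max(1, int(np.ceil(max(W, H) / max_edge)))
        return self._image[::factor, ::factor], float(factor)


@dataclass
class SlideMetadata:
    """Sidecar metadata stored next to a synthetic/TIFF slide."""

    mpp: float
    bounds_offset: tuple[int, int] = (0, 0)
    tissue_type: str = ""
    staining: str = ""
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mpp": self.mpp,
                "bounds_offset": list(self.bounds_offset),
                "tissue_type": self.tissue_type,
                "staining": self.staining,
                **self.extra,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SlideMetadata":
        data = json.loads(text)
        known = {"mpp", "bounds_offset", "tissue_type", "staining"}
        return cls(
            mpp=float(data["mpp"]),
            bounds_offset=tuple(data.get("bounds_offset", (0, 0))),
            tissue_type=data.get("tissue_type", ""),
            staining=data.get("staining", ""),
            extra={k: v for k, v in data.items() if k not in known},
        )


def sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".meta.json")


def resolve_slide_path(location: Union[str, Path]) -> tuple[Path, str]:
    """Resolve an order's WSI location to an image file and a format tag.

    Follows the scanner path conventions: a directory containing
    ``Slidedat.ini`` is an ``.mrxs`` container (the payload image lives
    inside it), while ``.svs``/``.tif``/``.tiff`` paths are plain files.
    """
    path = Path(location)
    if path.is_dir():
        if not (path / "Slidedat.ini").exists():
            raise SlideIOError(
                f"{path} is a directory but has no Slidedat.ini (not an "
                "mrxs container)"
            )
        candidates = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not candidates:
            raise SlideIOError(f"no image file inside mrxs container {path}")
        return candidates[0], "mrxs"
    if not path.exists():
        raise SlideIOError(f"slide not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".svs":
        return path, "svs"
    if suffix in (".tif", ".tiff"):
        return path, "tiff"
    raise SlideIOError(f"unsupported slide format: {path}")


def open_slide(
    location: Union[str, Path],
    metadata: Optional[SlideMetadata] = None,
) -> SlideReader:
    """Open a slide from an order's location string.

    Metadata (mpp, bounds offset, tissue/stain) comes from the JSON
    sidecar written next to the image unless supplied explicitly.
    """
    image_path, fmt = resolve_slide_path(location)
    if metadata is None:
        sc = sidecar_path(image_path)
        if not sc.exists():
            raise SlideIOError(f"missing metadata sidecar for {image_path}")
        metadata = SlideMetadata.from_json(sc.read_text(encoding="utf-8"))
    try:
        image = tifffile.imread(image_path)
    except (OSError, ValueError) as exc:
        raise SlideIOError(f"cannot read {image_path}: {exc}") from exc
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    x0, y0 = metadata.bounds_offset
    h, w = image.shape[:2]
    ref = SlideRef(
        path=str(location),
        format=fmt,
        mpp=metadata.mpp,
        dimensions=(w + x0, h + y0),
        bounds_offset=(x0, y0),
        tissue_type=metadata.tissue_type,
        staining=metadata.staining,
    )
    if x0 or y0:
        # Embed the imaged region at its scanner-frame origin so pixel
        # access is uniform across formats with and without an offset.
        full = np.full((h + y0, w + x0, 3), 255, dtype=image.dtype)
        full[y0:, x0:] = image
        image = full
    return SlideReader(ref, image)
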