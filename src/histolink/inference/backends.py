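"""Tissue segmentation, tile-grid generation, and the synthetic backend.

``segment_and_patch`` reproduces the front half of the patch-level
toolbox contract: threshold the slide thumbnail into a tissue mask,
then lay a regular tile grid over the masked regions at the model's
patching geometry. The synthetic model backend fills the back half:
per-tile class scores and attention scores that are a pure,
reproducible function of (seed, slide, model), so the whole loop can be
exercised without any network weights.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from histolink.errors import ContractError, ValidationError
from histolink.inference.postprocess import percentile_rank, risk_from_logits
from histolink.inference.tables import (
    ATTENTION_COLUMNS,
    ATTENTION_COLUMNS_NORMALIZED,
    SLIDE_COLUMNS,
    patch_table_columns,
)
from histolink.registry import ModelSpec, Patching
from histolink.slides import SlideReader

#: Minimum fraction of a tile covered by tissue mask for it to enter the grid.
TISSUE_FRACTION = 0.25

#: Gray level above which a pixel is unconditionally background (bright glass).
BACKGROUND_LEVEL = 220


@dataclass
class TileGrid:
    """Tile rectangles in base pixels, scanner (un-offset-corrected) frame."""

    tiles: list[tuple[int, int, int, int]]  # (x, y, width, height)
    patch_size_px: int
    spacing_mpp: float

    def __post_init__(self) -> None:
        if len(set(self.tiles)) != len(self.tiles):
            raise ValidationError("duplicate tiles in grid")
        for x, y, w, h in self.tiles:
            if w != h:
                raise ValidationError("tiles must be square")
            if x < 0 or y < 0:
                raise ValidationError("tile coordinates must be non-negative")

    def __len__(self) -> int:
        return len(self.tiles)


def tile_side_base_px(patching: Patching, slide_mpp: float) -> int:
    """Tile edge in base pixels: patch size scaled by spacing / slide mpp."""
    return int(round(patching.patch_size_px * patching.spacing_mpp / slide_mpp))


def tissue_mask(reader: SlideReader) -> tuple[np.ndarray, float]:
    """Boolean tissue mask on a downsampled grid, plus the downsample factor.

    Otsu threshold on the grayscale thumbnail (tissue is darker than the
    bright glass background) followed by small-object removal. A nearly
    uniform thumbnail (blank slide) yields an empty mask.
    """
    thumb, factor = reader.thumbnail()
    gray = thumb.mean(axis=2)
    if gray.max() - gray.min() < 10:
        return np.zeros(gray.shape, dtype=bool), factor
    threshold = threshold_otsu(gray)
    mask = (gray < threshold) & (gray < BACKGROUND_LEVEL)
    mask = remove_small_objects(mask, max_size=16)
    return mask, factor


def segment_and_patch(
    reader: SlideReader, patching: Patching
) -> tuple[bytes, TileGrid]:
    """Tissue mask (JPEG bytes) and the tile grid covering masked regions.

    Tiles are laid on a regular non-overlapping grid starting at the
    slide's bounds offset; a tile is kept when at least
    ``TISSUE_FRACTION`` of it overlaps the mask. A blank slide yields a
    valid empty grid.
    """
    mask, factor = tissue_mask(reader)
    side = tile_side_base_px(patching, reader.ref.mpp)
    W, H = reader.ref.dimensions
    x0, y0 = reader.ref.bounds_offset
    tiles: list[tuple[int, int, int, int]] = []
    for y in range(y0, H - side + 1, side):
        for x in range(x0, W - side + 1, side):
            mx0, my0 = int(x / factor), int(y / factor)
            mx1 = max(mx0 + 1, int(np.ceil((x + side) / factor)))
            my1 = max(my0 + 1, int(np.ceil((y + side) / factor)))
            window = mask[my0:my1, mx0:mx1]
            if window.size and window.mean() >= TISSUE_FRACTION:
                tiles.append((x, y, side, side))
    buf = io.BytesIO()
    Image.fromarray((mask * 255).astype(np.uint8)).save(
        buf, format="JPEG", quality=90
    )
    return buf.getvalue(), TileGrid(tiles, patching.patch_size_px,
                                    patching.spacing_mpp)


# ---------------------------------------------------------------------------
# Synthetic deterministic scoring


def _stable_uniform(*keys: int) -> float:
    """Uniform in [0, 1), a pure function of the integer key tuple."""
    ss = np.random.SeedSequence([int(k) & 0xFFFFFFFF for k in keys])
    return float(ss.generate_state(1)[0]) / 2.0**32


def _slide_key(reader: SlideReader) -> int:
    # Basename, not the full path: temp-dir prefixes must not change scores.
    name = Path(reader.ref.path).name
    w, h = reader.ref.dimensions
    return zlib.crc32(name.encode("utf-8")) ^ (w * 1_000_003 + h)


def _model_key(spec: ModelSpec) -> int:
    return zlib.crc32(spec.name.encode("utf-8"))


def run_patch_model(
    reader: SlideReader, spec: ModelSpec, grid: TileGrid, seed: int
) -> pd.DataFrame:
    """Per-tile class probabilities for a patch-level model.

    Scores are deterministic in (seed, slide, model, tile coordinates).
    Multi-column outputs are normalized to sum to 1 per tile; a
    single-class model keeps its raw score in [0, 1].
    """
    if not spec.is_patch_level:
        raise ContractError(f"{spec.name} is not a patch-level model")
    mk = _model_key(spec)
    sk = _slide_key(reader)
    rows = []
    for x, y, w, h in grid.tiles:
        raw = [
            _stable_uniform(seed, sk, mk, c, x, y)
            for c in range(len(spec.classes))
        ]
        if len(raw) > 1:
            total = sum(raw)
            raw = [r / total for r in raw]
        rows.append([x, y, h, w] + raw)
    return pd.DataFrame(rows, columns=patch_table_columns(spec.classes))


def run_mil_model(
    reader: SlideReader, spec: ModelSpec, grid: TileGrid, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slide-level prediction table and per-tile attention table.

    The attention table has six columns on the MIL-builtin path and
    seven on the attention-MIL path (normalized attention inserted
    before the percentile column). The slide table has one row per
    class: probabilities for classification models, per-time-bin logits
    for survival models.
    """
    if not spec.is_slide_level:
        raise ContractError(f"{spec.name} is not a slide-level model")
    if len(grid) == 0:
        raise ContractError("cannot run a MIL model on an empty tile grid")
    mk = _model_key(spec)
    sk = _slide_key(reader)

    attention = [
        _stable_uniform(seed, sk, mk, 0x0A, x, y) for x, y, _, _ in grid.tiles
    ]
    percentiles = percentile_rank(attention)
    geometry = [[x, y, h, w] for x, y, w, h in grid.tiles]
    if spec.toolbox == "marugoto":
        lo, hi = min(attention), max(attention)
        span = (hi - lo) or 1.0
        normalized = [(a - lo) / span for a in attention]
        att_df = pd.DataFrame(
            [g + [a, n, p] for g, a, n, p in
             zip(geometry, attention, normalized, percentiles)],
            columns=ATTENTION_COLUMNS_NORMALIZED,
        )
    else:
        att_df = pd.DataFrame(
            [g + [a, p] for g, a, p in zip(geometry, attention, percentiles)],
            columns=ATTENTION_COLUMNS,
        )

    n_classes = len(spec.classes)
    if spec.task_kind == "slide_mil_survival":
        values = [
            4.0 * _stable_uniform(seed, sk, mk, 0x0B, c) - 2.0
            for c in range(n_classes)
        ]
    else:
        raw = [
            _stable_uniform(seed, sk, mk, 0x0B, c) for c in range(n_classes)
        ]
        total = sum(raw)
        values = [r / total for r in raw]
    slide_df = pd.DataFrame(
        {"class": list(spec.classes), "probability": values},
        columns=SLIDE_COLUMNS,
    )
    return slide_df, att_df


def slide_level_summary(
    spec: ModelSpec, slide_table: pd.DataFrame
) -> tuple[str, float]:
    """Predicted label and score (or risk class and risk score)."""
    if spec.task_kind == "slide_mil_survival":
        logits = slide_table["probability"].tolist()
        score, risk_class = risk_from_logits(logits, spec.risk)
        return risk_class, score
    idx = int(np.argmax(slide_table["probability"].to_numpy()))
    return str(slide_table["class"].iloc[idx]), float(
        slide_table["probability"].iloc[idx]
    )
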