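"""Reviewable heatmap overlays from inference tables.

Three overlay styles mirror the three classes of models:

* **measurement maps** (binary patch models) — every tile polygon carries
  the prediction score of one clinically chosen target class, rendered
  by the viewer as a continuous color scale;
* **color maps** (multi-class patch models) — each tile is classed by the
  argmax of its class scores and colored by class;
* **density maps** (attention-MIL models) — each tile gets a polygon plus
  a cluster of 1–9 point detections proportional to its
  percentile-ranked attention, so high-attention regions read as dense
  hotspots; the project description summarizes the slide-level call.

Projects export as a GeoJSON FeatureCollection (detection conventions:
``classification`` name + packed RGB color, named measurements) plus a
JSON manifest, importable into the viewer via its standard GeoJSON
import.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from shapely.geometry import Point, Polygon, box, mapping, shape

from histolink.errors import DataError, ValidationError
from histolink.inference.backends import TileGrid
from histolink.registry import ModelSpec
from histolink.slides import SlideRef

#: Fixed palette keyed by class index (RGB). Distinct for up to 12 classes,
#: which covers every shipped model (max 9 classes).
PALETTE: list[tuple[int, int, int]] = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (170, 110, 40),
]


def class_colors(classes: Sequence[str]) -> dict[str, tuple[int, int, int]]:
    return {c: PALETTE[i % len(PALETTE)] for i, c in enumerate(classes)}


def pack_rgb(rgb: tuple[int, int, int]) -> int:
    r, g, b = rgb
    return (r << 16) | (g << 8) | b


def unpack_rgb(packed: int) -> tuple[int, int, int]:
    return ((packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF)


@dataclass
class DetectionObject:
    """One viewer detection: a tile polygon or an attention point."""

    geometry: Union[Polygon, Point]
    path_class: str
    measurements: dict[str, float] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionObject):
            return NotImplemented
        return (
            mapping(self.geometry) == mapping(other.geometry)
            and self.path_class == other.path_class
            and self.measurements == other.measurements
        )


@dataclass
class HeatmapProject:
    """A viewer-importable overlay for one slide and one model."""

    slide_path: str
    style: str  # measurement | color | density
    classes: dict[str, tuple[int, int, int]]
    detections: list[DetectionObject]
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if self.style not in ("measurement", "color", "density"):
            raise ValidationError(f"unknown style {self.style!r}")

    @property
    def polygons(self) -> list[DetectionObject]:
        return [d for d in self.detections if isinstance(d.geometry, Polygon)]

    @property
    def points(self) -> list[DetectionObject]:
        return [d for d in self.detections if isinstance(d.geometry, Point)]


# ---------------------------------------------------------------------------
# Coordinate handling


def offset_correct(
    tiles: Sequence[tuple[int, int, int, int]], slide: SlideRef
) -> list[tuple[int, int, int, int]]:
    """Translate tile rectangles from scanner frame to viewer frame.

    Subtracts the slide's bounds offset from every (x, y); formats
    without an offset (svs, synthetic) have (0, 0) and pass through.
    """
    x0, y0 = slide.bounds_offset
    corrected = []
    for x, y, w, h in tiles:
        nx, ny = x - x0, y - y0
        if nx < 0 or ny < 0:
            raise DataError(
                f"tile ({x}, {y}) lies before the bounds offset ({x0}, {y0})"
            )
        corrected.append((nx, ny, w, h))
    return corrected


def _table_tiles(table: pd.DataFrame) -> list[tuple[int, int, int, int]]:
    return [
        (int(r.x), int(r.y), int(r.width), int(r.height))
        for r in table.itertuples(index=False)
    ]


def _maybe_correct(
    tiles: list[tuple[int, int, int, int]], slide: Optional[SlideRef]
) -> list[tuple[int, int, int, int]]:
    return offset_correct(tiles, slide) if slide is not None else tiles


# ---------------------------------------------------------------------------
# Builders


def build_measurement_map(
    table: pd.DataFrame,
    spec: ModelSpec,
    slide: Optional[SlideRef] = None,
) -> HeatmapProject:
    """One polygon per tile, classed and measured by the target class."""
    if spec.visualization != "measurement":
        raise ValidationError(f"{spec.name} is not a measurement-map model")
    if spec.target_class is None:
        raise ValidationError(f"{spec.name} has no target class")
    if len(table) and spec.target_class not in table.columns:
        raise DataError(f"no column {spec.target_class!r} in table")
    tiles = _maybe_correct(_table_tiles(table), slide)
    scores = table[spec.target_class].tolist() if len(table) else []
    detections = [
        DetectionObject(
            box(x, y, x + w, y + h),
            spec.target_class,
            {spec.target_class: float(s)},
        )
        for (x, y, w, h), s in zip(tiles, scores)
    ]
    return HeatmapProject(
        slide_path=slide.path if slide else "",
        style="measurement",
        classes={spec.target_class: class_colors(spec.classes)[spec.target_class]},
        detections=detections,
    )


def build_color_map(
    table: pd.DataFrame,
    spec: ModelSpec,
    slide: Optional[SlideRef] = None,
) -> HeatmapProject:
    """One polygon per tile classed by argmax; ties go to the first class."""
    if spec.visualization != "color":
        raise ValidationError(f"{spec.name} is not a color-map model")
    from histolink.inference.postprocess import argmax_labels

    tiles = _maybe_correct(_table_tiles(table), slide)
    if len(table):
        labels, winning = argmax_labels(table, spec.classes)
    else:
        labels, winning = [], []
    detections = [
        DetectionObject(box(x, y, x + w, y + h), lab, {lab: float(s)})
        for (x, y, w, h), lab, s in zip(tiles, labels, winning)
    ]
    return HeatmapProject(
        slide_path=slide.path if slide else "",
        style="color",
        classes=class_colors(spec.classes),
        detections=detections,
    )


def density_points(p: float) -> int:
    """Detection points for a percentile-ranked attention score.

    ``min(9, max(1, floor(10 * p)))``: 9 points for p >= 0.9, 8 for
    p in [0.8, 0.9), ... down to 1 point for p < 0.2.
    """
    if not (0 < p <= 1):
        raise ValidationError(f"percentile score {p} outside (0, 1]")
    return min(9, max(1, math.floor(10 * p)))


#: Order in which the 3x3 sub-grid positions around a tile centre are
#: filled: centre first, then the ring row-major (offsets in units of a
#: quarter tile edge), so a single point sits exactly at the centre.
_POINT_OFFSETS = [
    (0, 0),
    (-1, -1), (0, -1), (1, -1),
    (-1, 0), (1, 0),
    (-1, 1), (0, 1), (1, 1),
]


def _tile_points(x: int, y: int, w: int, h: int, n: int) -> list[Point]:
    cx, cy = x + w / 2, y + h / 2
    qx, qy = w / 4, h / 4
    return [
        Point(cx + dx * qx, cy + dy * qy) for dx, dy in _POINT_OFFSETS[:n]
    ]


def summarize_slide(spec: ModelSpec, slide_label: str, slide_score: float) -> str:
    """Single-line summary shown as slide description in the slide tray."""
    return f"model: {spec.name}; prediction: {slide_label}; score: {slide_score:.2f}"


def build_density_map(
    table: pd.DataFrame,
    spec: ModelSpec,
    slide: Optional[SlideRef] = None,
    slide_label: Optional[str] = None,
    slide_score: Optional[float] = None,
) -> HeatmapProject:
    """Tile polygons plus attention-proportional point clusters.

    Each tile contributes one polygon (carrying both the raw and the
    percentile attention as measurements) and ``density_points(p)``
    point detections on a deterministic 3x3 sub-grid at the tile
    centre. When the slide-level call is supplied, it becomes the
    project description.
    """
    if spec.visualization != "density":
        raise ValidationError(f"{spec.name} is not a density-map model")
    tiles = _maybe_correct(_table_tiles(table), slide)
    attention_class = "attention"
    detections: list[DetectionObject] = []
    for (x, y, w, h), row in zip(tiles, table.itertuples(index=False)):
        p = float(row.percentile_attention)
        detections.append(
            DetectionObject(
                box(x, y, x + w, y + h),
                attention_class,
                {
                    "attention": float(row.attention),
                    "percentile_attention": p,
                },
            )
        )
        for pt in _tile_points(x, y, w, h, density_points(p)):
            detections.append(DetectionObject(pt, attention_class))
    description = None
    if slide_label is not None and slide_score is not None:
        description = summarize_slide(spec, slide_label, slide_score)
    return HeatmapProject(
        slide_path=slide.path if slide else "",
        style="density",
        classes={attention_class: PALETTE[0]},
        detections=detections,
        description=description,
    )


def build_project(
    spec: ModelSpec,
    bundle,
    slide: Optional[SlideRef] = None,
) -> HeatmapProject:
    """Dispatch to the builder matching the model's visualization style."""
    if spec.visualization == "measurement":
        return build_measurement_map(bundle.patch_table, spec, slide)
    if spec.visualization == "color":
        return build_color_map(bundle.patch_table, spec, slide)
    return build_density_map(
        bundle.attention_table, spec, slide,
        slide_label=bundle.slide_label, slide_score=bundle.slide_score,
    )


# ---------------------------------------------------------------------------
# GeoJSON export / import


def _feature(det: DetectionObject,
             colors: dict[str, tuple[int, int, int]]) -> dict:
    color = colors.get(det.path_class, PALETTE[0])
    return {
        "type": "Feature",
        "geometry": mapping(det.geometry),
        "properties": {
            "objectType": "detection",
            "classification": {
                "name": det.path_class,
                "color": pack_rgb(color),
            },
            "measurements": [
                {"name": k, "value": v} for k, v in det.measurements.items()
            ],
        },
    }


def export_project(project: HeatmapProject, out_dir: Union[str, Path]) -> Path:
    """Write the project as a GeoJSON + manifest bundle; returns the dir."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        collection = {
            "type": "FeatureCollection",
            "features": [
                _feature(d, project.classes) for d in project.detections
            ],
        }
        (out / "detections.geojson").write_text(
            json.dumps(collection), encoding="utf-8"
        )
        manifest = {
            "slide_path": project.slide_path,
            "style": project.style,
            "classes": {
                name: pack_rgb(rgb) for name, rgb in project.classes.items()
            },
            "description": project.description,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    except OSError as exc:
        raise DataError(f"cannot write project to {out}: {exc}") from exc
    return out


def import_project(project_dir: Union[str, Path]) -> HeatmapProject:
    """Inverse of :func:`export_project` (lossless round trip)."""
    d = Path(project_dir)
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    collection = json.loads(
        (d / "detections.geojson").read_text(encoding="utf-8")
    )
    detections = []
    for feat in collection["features"]:
        props = feat["properties"]
        detections.append(
            DetectionObject(
                shape(feat["geometry"]),
                props["classification"]["name"],
                {m["name"]: m["value"] for m in props["measurements"]},
            )
        )
    return HeatmapProject(
        slide_path=manifest["slide_path"],
        style=manifest["style"],
        classes={
            name: unpack_rgb(packed)
            for name, packed in manifest["classes"].items()
        },
        detections=detections,
        description=manifest["description"],
    )
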