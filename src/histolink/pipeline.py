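"""End-to-end processing of a single analysis order.

Glues the stages together: resolve the slide from the order's location,
segment and patch, run the model backend, assemble the inference
bundle, and build (optionally export) the heatmap project. The server
core calls this once per dispatched queue entry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from histolink import __version__
from histolink.heatmap import HeatmapProject, build_project, export_project
from histolink.inference import (
    InferenceBundle,
    assemble_bundle,
    run_mil_model,
    run_patch_model,
    segment_and_patch,
    slide_level_summary,
    top_k_tiles,
)
from histolink.registry import ModelSpec
from histolink.slides import SlideReader, open_slide


def run_inference(
    reader: SlideReader, spec: ModelSpec, seed: int = 0
) -> InferenceBundle:
    """Run one model on one slide and assemble the bundle."""
    mask_jpeg, grid = segment_and_patch(reader, spec.patching)
    metadata = {
        "model": spec.name,
        "task_kind": spec.task_kind,
        "toolbox": spec.toolbox,
        "classes": list(spec.classes),
        "patch_size_px": spec.patching.patch_size_px,
        "spacing_mpp": spec.patching.spacing_mpp,
        "slide_path": reader.ref.path,
        "slide_dimensions": list(reader.ref.dimensions),
        "slide_mpp": reader.ref.mpp,
        "bounds_offset": list(reader.ref.bounds_offset),
        "n_tiles": len(grid),
        "seed": seed,
        "software": f"histolink {__version__}",
    }
    if spec.is_patch_level:
        table = run_patch_model(reader, spec, grid, seed)
        top = []
        if spec.task_kind == "patch_binary" and len(table):
            top = top_k_tiles(table, spec.target_class, reader)
        return assemble_bundle(
            spec,
            run_metadata=metadata,
            mask_jpeg=mask_jpeg,
            patch_table=table,
            top_tiles=top,
            grid=grid,
        )
    slide_table, attention_table = run_mil_model(reader, spec, grid, seed)
    label, score = slide_level_summary(spec, slide_table)
    return assemble_bundle(
        spec,
        run_metadata=metadata,
        mask_jpeg=mask_jpeg,
        attention_table=attention_table,
        slide_table=slide_table,
        slide_label=label,
        slide_score=score,
        grid=grid,
    )


def process_order(
    wsi_location: Union[str, Path],
    spec: ModelSpec,
    *,
    seed: int = 0,
    project_dir: Optional[Union[str, Path]] = None,
) -> tuple[InferenceBundle, HeatmapProject]:
    """Open the slide, run inference, and build the heatmap project."""
    reader = open_slide(wsi_location)
    bundle = run_inference(reader, spec, seed)
    project = build_project(spec, bundle, reader.ref)
    if project_dir is not None:
        export_project(project, project_dir)
    return bundle, project
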