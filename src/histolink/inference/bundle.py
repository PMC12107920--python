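"""The inference bundle: everything one model run produces for one slide."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from histolink.errors import ContractError
from histolink.inference.backends import TileGrid
from histolink.inference.tables import (
    table_to_csv_bytes,
    validate_attention_table,
    validate_patch_table,
    validate_slide_table,
)
from histolink.registry import ModelSpec


@dataclass
class InferenceBundle:
    """Artifacts from one model run, composed according to the task kind.

    Patch-level models carry the tissue mask, the tile-prediction table
    and run metadata (binary models additionally the top-5 tile crops);
    slide-level models carry the slide table, the attention table and
    the summary label/score pair.
    """

    spec_name: str
    task_kind: str
    run_metadata: dict
    mask_jpeg: Optional[bytes] = None
    patch_table: Optional[pd.DataFrame] = None
    attention_table: Optional[pd.DataFrame] = None
    slide_table: Optional[pd.DataFrame] = None
    top_tiles: list[bytes] = field(default_factory=list)
    slide_label: Optional[str] = None
    slide_score: Optional[float] = None
    grid: Optional[TileGrid] = None

    def validate(self, spec: ModelSpec) -> None:
        if spec.name != self.spec_name or spec.task_kind != self.task_kind:
            raise ContractError(
                f"bundle ({self.spec_name}, {self.task_kind}) does not match "
                f"spec ({spec.name}, {spec.task_kind})"
            )
        if spec.is_patch_level:
            if self.mask_jpeg is None or self.patch_table is None:
                raise ContractError(
                    "patch-level bundle needs mask_jpeg and patch_table"
                )
            validate_patch_table(self.patch_table, spec.classes)
            if spec.task_kind == "patch_binary":
                if len(self.top_tiles) > 5:
                    raise ContractError("at most 5 top tiles")
            elif self.top_tiles:
                raise ContractError("tile gallery is for binary models only")
        else:
            if self.attention_table is None or self.slide_table is None:
                raise ContractError(
                    "slide-level bundle needs attention and slide tables"
                )
            validate_attention_table(
                self.attention_table, normalized=(spec.toolbox == "marugoto")
            )
            validate_slide_table(self.slide_table, spec.classes)
            if self.slide_label is None or self.slide_score is None:
                raise ContractError(
                    "slide-level bundle needs slide_label and slide_score"
                )

    def tile_csv_bytes(self) -> bytes:
        table = self.patch_table if self.patch_table is not None \
            else self.attention_table
        if table is None:
            raise ContractError("bundle has no tile table")
        return table_to_csv_bytes(table)

    def slide_csv_bytes(self) -> bytes:
        if self.slide_table is None:
            raise ContractError("bundle has no slide table")
        return table_to_csv_bytes(self.slide_table)

    def metadata_json_bytes(self) -> bytes:
        return json.dumps(
            self.run_metadata, indent=2, sort_keys=True
        ).encode("utf-8")


def assemble_bundle(spec: ModelSpec, **artifacts) -> InferenceBundle:
    """Build and validate a bundle for ``spec`` from keyword artifacts."""
    bundle = InferenceBundle(
        spec_name=spec.name, task_kind=spec.task_kind, **artifacts
    )
    bundle.validate(spec)
    return bundle
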