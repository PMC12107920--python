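"""Tabular output contracts of the inference toolboxes.

Three CSV schemas are emitted, mirroring the toolboxes the backends
emulate:

* tile predictions (patch-level models): one row per tile with ``x, y,
  height, width`` in base pixels followed by one probability column per
  class, in the model's class order;
* attention tables (MIL models): the four geometry columns plus the raw
  attention score and its percentile rank — six columns on the
  MIL-builtin path, seven on the attention-MIL path, which inserts the
  normalized attention before the percentile column;
* slide predictions: one row per class with the class name and its
  probability (survival models store one logit per time bin instead).

CSV dialect: comma-separated, header row, '.' decimal, no quoting
unless needed. Writers/readers round-trip tables bit-identically.
"""

from __future__ import annotations

import io
from typing import Sequence

import pandas as pd

from histolink.errors import ContractError

GEOMETRY_COLUMNS = ["x", "y", "height", "width"]
ATTENTION_COLUMNS = GEOMETRY_COLUMNS + ["attention", "percentile_attention"]
ATTENTION_COLUMNS_NORMALIZED = GEOMETRY_COLUMNS + [
    "attention", "normalized_attention", "percentile_attention",
]
SLIDE_COLUMNS = ["class", "probability"]


def patch_table_columns(classes: Sequence[str]) -> list[str]:
    return GEOMETRY_COLUMNS + list(classes)


def validate_patch_table(df: pd.DataFrame, classes: Sequence[str]) -> None:
    expected = patch_table_columns(classes)
    if list(df.columns) != expected:
        raise ContractError(
            f"patch table columns {list(df.columns)} != expected {expected}"
        )
    scores = df[list(classes)]
    if len(df) and not ((scores.values >= 0) & (scores.values <= 1)).all():
        raise ContractError("class scores must lie in [0, 1]")


def validate_attention_table(df: pd.DataFrame, normalized: bool) -> None:
    expected = ATTENTION_COLUMNS_NORMALIZED if normalized else ATTENTION_COLUMNS
    if list(df.columns) != expected:
        raise ContractError(
            f"attention table columns {list(df.columns)} != expected {expected}"
        )
    if len(df):
        p = df["percentile_attention"]
        if not ((p > 0) & (p <= 1)).all():
            raise ContractError("percentile_attention must lie in (0, 1]")


def validate_slide_table(df: pd.DataFrame, classes: Sequence[str]) -> None:
    if list(df.columns) != SLIDE_COLUMNS:
        raise ContractError(
            f"slide table columns {list(df.columns)} != expected {SLIDE_COLUMNS}"
        )
    if list(df["class"]) != list(classes):
        raise ContractError(
            f"slide table rows {list(df['class'])} != model classes {list(classes)}"
        )


def table_to_csv_bytes(df: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def table_from_csv_bytes(data: bytes) -> pd.DataFrame:
    # round_trip float parsing keeps write->read->write bit-identical
    return pd.read_csv(io.BytesIO(data), float_precision="round_trip")
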