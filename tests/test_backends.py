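"""Segmentation, tile grids, deterministic scoring, and post-processing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histolink.errors import ContractError, ValidationError
from histolink.inference import (
    percentile_rank,
    risk_from_logits,
    run_mil_model,
    run_patch_model,
    segment_and_patch,
    slide_level_summary,
    table_from_csv_bytes,
    table_to_csv_bytes,
    tile_side_base_px,
    top_k_tiles,
)
from histolink.registry import Patching, RiskConfig
from histolink.slides import SlideReader, SlideRef

from conftest import square_blob_reader


def blank_reader(size=1024, mpp=0.5):
    image = np.full((size, size, 3), 240, dtype=np.uint8)
    ref = SlideRef(path="synthetic://blank", format="synthetic",
                   mpp=mpp, dimensions=(size, size))
    return SlideReader(ref, image)


class TestSegmentAndPatch:
    def test_tiles_cluster_on_the_blob(self):
        reader = square_blob_reader(size=2048, blob_origin=(600, 700),
                                    blob_size=512, mpp=0.5)
        patching = Patching(patch_size_px=224, spacing_mpp=0.5)  # native
        _mask, grid = segment_and_patch(reader, patching)
        assert len(grid) > 0
        side = 224
        for x, y, w, h in grid.tiles:
            cx, cy = x + w / 2, y + h / 2
            # every tile centre inside the blob bbox dilated by one tile
            assert 600 - side <= cx <= 600 + 512 + side
            assert 700 - side <= cy <= 700 + 512 + side

    def test_blank_slide_yields_empty_grid(self):
        _mask, grid = segment_and_patch(
            blank_reader(), Patching(patch_size_px=224, spacing_mpp=0.5)
        )
        assert len(grid) == 0

    def test_tile_side_scales_with_spacing(self):
        # patch spacing twice the slide mpp doubles the base-pixel side
        assert tile_side_base_px(Patching(224, 1.0), slide_mpp=0.5) == 448
        assert tile_side_base_px(Patching(224, 0.5), slide_mpp=0.5) == 224
        reader = square_blob_reader(size=2048, mpp=0.5)
        _m, grid = segment_and_patch(reader, Patching(224, 1.0))
        assert all(w == 448 and h == 448 for _x, _y, w, h in grid.tiles)

    def test_mask_is_jpeg(self):
        mask_jpeg, _ = segment_and_patch(
            square_blob_reader(), Patching(224, 0.5)
        )
        assert mask_jpeg[:2] == b"\xff\xd8"  # JPEG SOI marker


@pytest.fixture(scope="module")
def grid_and_reader():
    reader = square_blob_reader(size=2048, blob_size=900,
                                blob_origin=(400, 400))
    _m, grid = segment_and_patch(reader, Patching(224, 0.5))
    return reader, grid


@pytest.fixture(scope="module")
def mil_grid_and_reader():
    reader = square_blob_reader(size=2048, blob_size=1200,
                                blob_origin=(300, 300), mpp=1.14)
    _m, grid = segment_and_patch(reader, Patching(224, 1.14))
    return reader, grid


class TestPatchModel:
    def test_schema_and_row_count(self, grid_and_reader, registry):
        reader, grid = grid_and_reader
        spec = registry.resolve("breast-tumor-resnet34.tcga-brca")
        table = run_patch_model(reader, spec, grid, seed=1)
        assert list(table.columns) == ["x", "y", "height", "width",
                                       "no-tumor", "tumor"]
        assert len(table) == len(grid)

    def test_same_seed_identical_different_seed_not(self, grid_and_reader,
                                                    registry):
        reader, grid = grid_and_reader
        spec = registry.resolve("colorectal-resnet34.penn")
        t1 = run_patch_model(reader, spec, grid, seed=5)
        t2 = run_patch_model(reader, spec, grid, seed=5)
        t3 = run_patch_model(reader, spec, grid, seed=6)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1.equals(t3)

    def test_scores_are_probabilities(self, grid_and_reader, registry):
        reader, grid = grid_and_reader
        spec = registry.resolve("colorectal-resnet34.penn")
        table = run_patch_model(reader, spec, grid, seed=2)
        scores = table[list(spec.classes)].to_numpy()
        assert ((scores >= 0) & (scores <= 1)).all()
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_argmax_label_holds_row_maximum(self, grid_and_reader, registry):
        from histolink.inference import argmax_labels

        reader, grid = grid_and_reader
        spec = registry.resolve("lung-tumor-resnet34.tcga-luad")
        table = run_patch_model(reader, spec, grid, seed=3)
        labels, winning = argmax_labels(table, spec.classes)
        maxima = table[list(spec.classes)].max(axis=1).tolist()
        assert winning == maxima
        for lab, w, (_i, row) in zip(labels, winning, table.iterrows()):
            assert row[lab] == w

    def test_csv_round_trip_bit_identical(self, grid_and_reader, registry):
        reader, grid = grid_and_reader
        spec = registry.resolve("breast-tumor-resnet34.tcga-brca")
        table = run_patch_model(reader, spec, grid, seed=1)
        data = table_to_csv_bytes(table)
        assert table_to_csv_bytes(table_from_csv_bytes(data)) == data


class TestMilModel:
    def test_binary_mil_slide_table(self, mil_grid_and_reader, registry):
        reader, grid = mil_grid_and_reader
        spec = registry.resolve("pancancer-tp53-mut.tcga")
        slide_df, att_df = run_mil_model(reader, spec, grid, seed=1)
        assert list(slide_df.columns) == ["class", "probability"]
        assert list(slide_df["class"]) == ["wildtype", "mutant"]
        assert np.isclose(slide_df["probability"].sum(), 1.0)
        assert list(att_df.columns) == [
            "x", "y", "height", "width", "attention", "percentile_attention"
        ]

    def test_attention_mil_path_has_seven_columns(self, mil_grid_and_reader,
                                                  registry):
        reader, grid = mil_grid_and_reader
        spec = registry.resolve("braf-attMIL-marugoto")
        _s, att_df = run_mil_model(reader, spec, grid, seed=1)
        assert list(att_df.columns) == [
            "x", "y", "height", "width", "attention",
            "normalized_attention", "percentile_attention",
        ]
        assert att_df["normalized_attention"].min() == 0.0
        assert att_df["normalized_attention"].max() == 1.0

    def test_max_percentile_is_one(self, mil_grid_and_reader, registry):
        reader, grid = mil_grid_and_reader
        spec = registry.resolve("pancancer-tp53-mut.tcga")
        _s, att_df = run_mil_model(reader, spec, grid, seed=4)
        assert att_df["percentile_attention"].max() == 1.0

    def test_survival_model_has_four_logit_rows(self, mil_grid_and_reader,
                                                registry):
        reader, grid = mil_grid_and_reader
        spec = registry.resolve("gbmlgg-survival-porpoise.tcga")
        slide_df, _a = run_mil_model(reader, spec, grid, seed=1)
        assert list(slide_df["class"]) == [
            "logits-time0", "logits-time1", "logits-time2", "logits-time3"
        ]
        label, score = slide_level_summary(spec, slide_df)
        assert label in ("low", "high")
        assert score == pytest.approx(slide_df["probability"].sum())


def rank_oracle(values):
    """Brute-force fractional average rank: ties share the mean position."""
    n = len(values)
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append((less + (equal + 1) / 2) / n)
    return out


class TestPercentileRank:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([5, 1, 3], [1.0, 1 / 3, 2 / 3]),
            ([7, 7, 7], [2 / 3, 2 / 3, 2 / 3]),
            ([4.2], [1.0]),
        ],
    )
    def test_hand_computed_examples(self, scores, expected):
        assert percentile_rank(scores) == pytest.approx(expected)

    def test_empty_list_raises(self):
        with pytest.raises(ValidationError):
            percentile_rank([])

    @given(
        st.lists(
            st.integers(min_value=-5, max_value=5), min_size=1, max_size=40
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle_with_ties(self, values):
        got = percentile_rank([float(v) for v in values])
        expected = rank_oracle(values)
        assert all(math.isclose(g, e, rel_tol=1e-12)
                   for g, e in zip(got, expected))


class TestTopKTiles:
    def make_table(self, scores):
        rows = []
        for i, s in enumerate(scores):
            rows.append({"x": (i % 4) * 100, "y": (i // 4) * 100,
                         "height": 100, "width": 100,
                         "neg": 1 - s, "pos": s})
        return pd.DataFrame(rows, columns=["x", "y", "height", "width",
                                           "neg", "pos"])

    def test_returns_exactly_five_for_large_grids(self):
        reader = square_blob_reader(size=1024)
        table = self.make_table([i / 20 for i in range(20)])
        assert len(top_k_tiles(table, "pos", reader)) == 5

    def test_truncates_on_small_grids(self):
        reader = square_blob_reader(size=1024)
        table = self.make_table([0.1, 0.5, 0.9])
        assert len(top_k_tiles(table, "pos", reader)) == 3

    def test_tie_break_matches_brute_force_sort(self):
        reader = square_blob_reader(size=1024)
        table = self.make_table([0.9, 0.9, 0.8, 0.7, 0.9, 0.6, 0.5, 0.4])
        ranked = sorted(
            table.to_dict("records"),
            key=lambda r: (-r["pos"], r["y"], r["x"]),
        )[:5]
        crops = top_k_tiles(table, "pos", reader)
        expected = [
            reader.read_region(int(r["x"]), int(r["y"]), 100, 100)
            for r in ranked
        ]
        from io import BytesIO

        from PIL import Image

        got = [np.asarray(Image.open(BytesIO(c))) for c in crops]
        # JPEG is lossy; compare the underlying regions' mean intensities
        for g, e in zip(got, expected):
            assert abs(float(g.mean()) - float(e.mean())) < 3.0

    def test_missing_target_column_raises(self):
        reader = square_blob_reader(size=1024)
        with pytest.raises(ContractError):
            top_k_tiles(self.make_table([0.5]), "tumor", reader)


class TestRiskFromLogits:
    def test_zero_logits_give_zero_risk_and_low_class(self):
        score, cls = risk_from_logits([0, 0, 0, 0], RiskConfig("logit_sum", 0.0))
        assert score == 0.0
        assert cls == "low"  # exactly at the median threshold => low

    def test_above_median_is_high(self):
        score, cls = risk_from_logits([1, 1, 0, 0], RiskConfig("logit_sum", 0.0))
        assert score == 2.0
        assert cls == "high"

    @given(
        logits=st.lists(
            st.floats(min_value=-3, max_value=3, allow_nan=False),
            min_size=4, max_size=4,
        ),
        bin_index=st.integers(min_value=0, max_value=3),
        bump=st.floats(min_value=0.01, max_value=2),
    )
    @settings(max_examples=200, deadline=None)
    @pytest.mark.parametrize(
        "formula", ["logit_sum", "neg_cumulative_survival"]
    )
    def test_monotone_in_hazard(self, formula, logits, bin_index, bump):
        config = RiskConfig(formula, 0.0)
        base, _ = risk_from_logits(logits, config)
        bumped = list(logits)
        bumped[bin_index] += bump
        higher, _ = risk_from_logits(bumped, config)
        assert higher >= base

    def test_unknown_formula_raises(self):
        with pytest.raises(ValidationError):
            risk_from_logits([0.0], RiskConfig("nonsense", 0.0))
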