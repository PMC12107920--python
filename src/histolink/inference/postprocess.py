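"""Shared post-processing of raw model outputs.

Covers the steps every backend path needs after scoring: percentile
ranking of attention scores (fractional average rank, as produced by
``pandas.Series.rank(pct=True)``), argmax labelling, the top-k tile
gallery for binary patch models, and the survival risk split.
"""

from __future__ import annotations

import io
import math
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from histolink.errors import ContractError, ValidationError
from histolink.registry import RiskConfig
from histolink.slides import SlideReader


def percentile_rank(scores: Sequence[float]) -> list[float]:
    """Fractional average-rank percentiles in (0, 1].

    ``p_i`` is the average rank of ``score_i`` (ties share the mean of
    their rank positions) divided by the number of scores; the maximum
    always maps to 1.0.
    """
    if len(scores) == 0:
        raise ValidationError("cannot percentile-rank an empty list")
    return pd.Series(list(scores), dtype=float).rank(pct=True).tolist()


def argmax_labels(
    table: pd.DataFrame, classes: Sequence[str]
) -> tuple[list[str], list[float]]:
    """Winning class and score per tile; ties go to the first class."""
    scores = table[list(classes)].to_numpy()
    idx = scores.argmax(axis=1)  # argmax takes the first maximum
    labels = [classes[i] for i in idx]
    winning = scores[np.arange(len(idx)), idx].tolist()
    return labels, winning


def top_k_tiles(
    table: pd.DataFrame,
    target_class: str,
    reader: SlideReader,
    k: int = 5,
    *,
    jpeg_quality: int = 90,
) -> list[bytes]:
    """JPEG crops of the k tiles scoring highest for ``target_class``.

    Tiles are cropped from the slide at native resolution and returned
    in descending-score order; ties break deterministically by
    (score desc, y asc, x asc). Fewer than k crops are returned when the
    grid is smaller.
    """
    if target_class not in table.columns:
        raise ContractError(f"no column {target_class!r} in prediction table")
    ranked = table.sort_values(
        by=[target_class, "y", "x"], ascending=[False, True, True]
    ).head(k)
    crops: list[bytes] = []
    for row in ranked.itertuples(index=False):
        region = reader.read_region(
            int(row.x), int(row.y), int(row.width), int(row.height)
        )
        buf = io.BytesIO()
        Image.fromarray(region).save(buf, format="JPEG", quality=jpeg_quality)
        crops.append(buf.getvalue())
    return crops


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _risk_logit_sum(logits: Sequence[float]) -> float:
    """Sum of per-time-bin log-odds hazards.

    A documented stand-in for the published per-model risk formulas
    (which are referenced on the model hubs but not reproduced here):
    zero for all-zero logits and strictly increasing in every
    hazard-increasing logit.
    """
    return float(sum(logits))


def _risk_neg_cumulative_survival(logits: Sequence[float]) -> float:
    """Negative sum of cumulative survival over time bins.

    Discrete-hazard form: each logit is a log-odds hazard, survival at
    bin t is the product of (1 - hazard) up to t, and the risk score is
    minus the sum of the survival curve. Also a labelled stand-in.
    """
    survival = 1.0
    total = 0.0
    for logit in logits:
        survival *= 1.0 - _sigmoid(logit)
        total += survival
    return -total


RISK_FORMULAS = {
    "logit_sum": _risk_logit_sum,
    "neg_cumulative_survival": _risk_neg_cumulative_survival,
}


def risk_from_logits(
    logits: Sequence[float], risk_config: RiskConfig
) -> tuple[float, str]:
    """Risk score and class from survival-model time-bin logits.

    The formula is pluggable via ``risk_config.formula_id``; the class is
    ``high`` iff the score is strictly greater than the configured median
    threshold (a score exactly at the median is low risk).
    """
    if risk_config is None:
        raise ValidationError("survival model requires a risk config")
    try:
        formula = RISK_FORMULAS[risk_config.formula_id]
    except KeyError:
        raise ValidationError(
            f"unknown risk formula {risk_config.formula_id!r}"
        ) from None
    score = formula(list(logits))
    risk_class = "high" if score > risk_config.median_threshold else "low"
    return score, risk_class
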