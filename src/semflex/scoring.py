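"""Fluency, originality and flexibility scores for divergent-thinking responses.

Flexibility is scored as the semantic distance between *consecutive*
responses: responses 1-2 form the first pair, 2-3 the second, and so on,
preserving the order of generation.  Large pair distances indicate a
jump between semantic categories (flexible ideation); small distances
indicate staying within a category.  Originality is the semantic
distance between the prompt and each response.  Both are aggregated per
item as sum, mean and maximum; the sum rises mechanically with the
number of responses (the fluency confound), which the mean and maximum
aggregations are designed to correct.

The mean divides the pair-distance sum by the *fluency* n (the number of
responses), not by the pair count n - 1; the ``mean_divisor="pairs"``
option selects the n - 1 variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingModel, WeightTable
from .vectorize import ResponseRecord, ResponseVector, vectorize_response

logger = logging.getLogger(__name__)

__all__ = [
    "PairScore",
    "ItemScores",
    "BatteryScores",
    "DuplicateOrderError",
    "semantic_distance",
    "angle_degrees",
    "consecutive_pairs",
    "score_item",
    "aggregate_battery",
    "read_responses",
    "score_table",
    "score_matrix",
    "ITEM_COLUMNS",
]

ITEM_COLUMNS = [
    "participant_id",
    "item_id",
    "fluency",
    "flex_sum",
    "flex_mean",
    "flex_max",
    "orig_sum",
    "orig_mean",
    "orig_max",
    "n_pairs_scored",
]


class DuplicateOrderError(ValueError):
    """A participant x item group contains a repeated order index."""


@dataclass
class PairScore:
    """Distance between responses at adjacent order indices."""

    first_order_index: int
    second_order_index: int
    distance: float | None = None
    angle_degrees: float | None = None


@dataclass
class ItemScores:
    """All per-item scores for one participant on one prompt.

    Undefined aggregates are ``None`` (e.g. no scorable pair), never 0 —
    a zero is meaningful, marking identical adjacent ideas.
    """

    participant_id: str
    item_id: str
    fluency: int
    flex_sum: float | None
    flex_mean: float | None
    flex_max: float | None
    orig_sum: float | None
    orig_mean: float | None
    orig_max: float | None
    n_pairs_scored: int


@dataclass
class BatteryScores:
    """Per-participant summary across the items of a battery."""

    participant_id: str
    items: dict[str, ItemScores]
    fluency_mean_across_items: float
    fluency_max_across_items: int


def _as_array(v: ResponseVector | np.ndarray | Sequence[float] | None) -> np.ndarray | None:
    if v is None:
        return None
    if isinstance(v, ResponseVector):
        return v.vector
    return np.asarray(v, dtype=float)


def semantic_distance(
    u: ResponseVector | np.ndarray | None, v: ResponseVector | np.ndarray | None
) -> float | None:
    """Cosine distance ``1 - cos(u, v)`` in [0, 2]; ``None`` if either is undefined."""
    ua, va = _as_array(u), _as_array(v)
    if ua is None or va is None:
        return None
    cos = float(np.dot(ua, va) / (np.linalg.norm(ua) * np.linalg.norm(va)))
    return float(np.clip(1.0 - cos, 0.0, 2.0))


def angle_degrees(
    u: ResponseVector | np.ndarray | None, v: ResponseVector | np.ndarray | None
) -> float | None:
    """Angle between the two response vectors in degrees, in [0, 180]."""
    d = semantic_distance(u, v)
    if d is None:
        return None
    return math.degrees(math.acos(np.clip(1.0 - d, -1.0, 1.0)))


def consecutive_pairs(responses: Sequence[ResponseRecord]) -> list[PairScore]:
    """Adjacent-response pair skeletons, order preserved: n responses -> n - 1 pairs.

    ``responses`` must belong to a single participant x item group and be
    sorted by order index; a duplicated order index is a data error.
    """
    seen: set[int] = set()
    for rec in responses:
        if rec.order_index in seen:
            raise DuplicateOrderError(
                f"duplicate order_index {rec.order_index} for participant "
                f"{rec.participant_id!r}, item {rec.item_id!r}"
            )
        seen.add(rec.order_index)
    return [
        PairScore(responses[i].order_index, responses[i + 1].order_index)
        for i in range(len(responses) - 1)
    ]


def _aggregate(values: list[float], fluency: int, divisor: int) -> tuple[
    float | None, float | None, float | None
]:
    if not values:
        return None, None, None
    total = float(sum(values))
    return total, total / divisor if divisor > 0 else None, float(max(values))


def score_item(
    responses: Sequence[ResponseRecord],
    model: EmbeddingModel,
    weights: WeightTable | None = None,
    stoplist: Iterable[str] | None = None,
    prompt_text: str | None = None,
    mean_divisor: str = "fluency",
    metric: str = "cosine-distance",
) -> ItemScores:
    """Score one participant x item response sequence.

    Fluency counts every ingested response, including ones whose vector
    is undefined; undefined vectors are excluded from pair and
    originality sums but still inflate the mean's divisor.  ``metric``
    selects the pair-score scale: cosine distance (default) or the angle
    in degrees.
    """
    if mean_divisor not in ("fluency", "pairs"):
        raise ValueError("mean_divisor must be 'fluency' or 'pairs'")
    if metric not in ("cosine-distance", "angle-degrees"):
        raise ValueError("metric must be 'cosine-distance' or 'angle-degrees'")
    measure = semantic_distance if metric == "cosine-distance" else angle_degrees

    records = sorted(responses, key=lambda r: r.order_index)
    pairs = consecutive_pairs(records)
    vecs = [vectorize_response(r.text, model, weights, stoplist) for r in records]
    n_undef = sum(1 for v in vecs if not v.defined)
    if n_undef:
        pid = records[0].participant_id if records else "?"
        iid = records[0].item_id if records else "?"
        logger.warning(
            "participant %s, item %s: %d response(s) with undefined vector "
            "(stoplisted or out-of-vocabulary); excluded from pair/originality sums",
            pid, iid, n_undef,
        )

    fluency = len(records)
    divisor = fluency if mean_divisor == "fluency" else max(fluency - 1, 0)

    pair_values: list[float] = []
    for i, pair in enumerate(pairs):
        pair.distance = semantic_distance(vecs[i], vecs[i + 1])
        pair.angle_degrees = angle_degrees(vecs[i], vecs[i + 1])
        value = pair.distance if metric == "cosine-distance" else pair.angle_degrees
        if value is not None:
            pair_values.append(value)
    flex_sum, flex_mean, flex_max = _aggregate(pair_values, fluency, divisor)

    orig_sum = orig_mean = orig_max = None
    if prompt_text is not None:
        prompt_vec = vectorize_response(prompt_text, model, weights, stoplist)
        if prompt_vec.defined:
            orig_values = [
                d for v in vecs if (d := measure(prompt_vec, v)) is not None
            ]
            orig_sum, orig_mean, orig_max = _aggregate(orig_values, fluency, fluency)
        else:
            pid = records[0].participant_id if records else "?"
            logger.warning("prompt %r is not vectorizable; originality undefined", prompt_text)

    item_id = records[0].item_id if records else ""
    participant_id = records[0].participant_id if records else ""
    return ItemScores(
        participant_id=participant_id,
        item_id=item_id,
        fluency=fluency,
        flex_sum=flex_sum,
        flex_mean=flex_mean,
        flex_max=flex_max,
        orig_sum=orig_sum,
        orig_mean=orig_mean,
        orig_max=orig_max,
        n_pairs_scored=len(pair_values),
    )


def aggregate_battery(item_scores: Sequence[ItemScores]) -> BatteryScores:
    """Combine one participant's per-item scores into a battery summary."""
    if not item_scores:
        raise ValueError("aggregate_battery requires at least one ItemScores")
    pids = {s.participant_id for s in item_scores}
    if len(pids) != 1:
        raise ValueError(f"item scores span multiple participants: {sorted(pids)}")
    items: dict[str, ItemScores] = {}
    for s in item_scores:
        if s.item_id in items:
            raise ValueError(f"duplicate item {s.item_id!r} for participant {s.participant_id!r}")
        items[s.item_id] = s
    fluencies = [s.fluency for s in item_scores]
    return BatteryScores(
        participant_id=item_scores[0].participant_id,
        items=items,
        fluency_mean_across_items=float(sum(fluencies)) / len(fluencies),
        fluency_max_across_items=int(max(fluencies)),
    )


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read the comma-separated response table.

    Expected header: ``participant_id,item_id,order_index,response``.
    Rows whose response text is empty after stripping are dropped with a
    warning.  Rows need not be pre-sorted.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str})
    required = {"participant_id", "item_id", "order_index", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    text = df["response"].fillna("").astype(str).str.strip()
    n_empty = int((text == "").sum())
    if n_empty:
        logger.warning("%s: dropped %d row(s) with empty response text", path, n_empty)
    df = df.loc[text != ""].copy()
    df["response"] = text[text != ""]
    df["order_index"] = df["order_index"].astype(int)
    return df


def score_table(
    responses: pd.DataFrame,
    model: EmbeddingModel,
    weights: WeightTable | None = None,
    stoplist: Iterable[str] | None = None,
    prompts: Mapping[str, str] | None = None,
    mean_divisor: str = "fluency",
    metric: str = "cosine-distance",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every participant x item group of a response table.

    ``prompts`` maps item id to the prompt text used for originality; by
    default the item id itself is the prompt (the convention of response
    tables whose item column holds the prompt word, e.g. "bottle").
    Returns the per-item score table and the per-participant battery
    summary; scoring is a pure per-group computation, so the result is
    invariant to row order in the input.
    """
    item_rows: list[ItemScores] = []
    by_participant: dict[str, list[ItemScores]] = {}
    keys = responses[["participant_id", "item_id"]].drop_duplicates()
    for pid, iid in keys.itertuples(index=False):
        group = responses[
            (responses["participant_id"] == pid) & (responses["item_id"] == iid)
        ].sort_values("order_index")
        records = [
            ResponseRecord(str(pid), str(iid), int(r.order_index), str(r.response))
            for r in group.itertuples(index=False)
        ]
        prompt = prompts.get(str(iid), str(iid)) if prompts is not None else str(iid)
        scores = score_item(
            records, model, weights, stoplist, prompt, mean_divisor=mean_divisor, metric=metric
        )
        item_rows.append(scores)
        by_participant.setdefault(str(pid), []).append(scores)

    item_df = pd.DataFrame(
        [
            {col: getattr(s, col) for col in ITEM_COLUMNS}
            for s in sorted(item_rows, key=lambda s: (s.participant_id, s.item_id))
        ],
        columns=ITEM_COLUMNS,
    )
    battery_rows = []
    for pid in sorted(by_participant):
        b = aggregate_battery(by_participant[pid])
        battery_rows.append(
            {
                "participant_id": b.participant_id,
                "n_items": len(b.items),
                "fluency_mean_across_items": b.fluency_mean_across_items,
                "fluency_max_across_items": b.fluency_max_across_items,
            }
        )
    battery_df = pd.DataFrame(
        battery_rows,
        columns=[
            "participant_id",
            "n_items",
            "fluency_mean_across_items",
            "fluency_max_across_items",
        ],
    )
    return item_df, battery_df


def score_matrix(item_df: pd.DataFrame, value: str) -> pd.DataFrame:
    """Pivot a per-item score table to participants x items for one score column.

    Undefined scores become missing cells (never zeros), matching the
    score-matrix format the psychometrics operations read.
    """
    if value not in ITEM_COLUMNS:
        raise ValueError(f"unknown score column {value!r}")
    return item_df.pivot(index="participant_id", columns="item_id", values=value)
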