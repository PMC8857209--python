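"""Accuracy metrics for single-step biocatalytic reaction prediction.

Implements the evaluation protocol used to compare forward/backward models
trained under the EC token schemes: top-k accuracy (exact canonical-string
match of the full payload), backward EC-only accuracy, round-trip accuracy
(a backward proposal counts when the forward model's rank-1 product
regenerates the target), per-EC-class breakdowns and the level-1 class
confusion matrix.

Matching is exact canonical-SMILES equality, stereochemistry included; an
``ignore_stereo`` switch recomputes a metric on stereo-stripped strings
(useful for isomerase-dominated sets, where stereochemical assignment is
the dominant failure mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .chem_core import ECNumber, strip_stereo, truncate_ec
from .predict import (
    BackwardPredictor,
    BackwardQuery,
    ForwardPredictor,
    ForwardQuery,
    SingleStepPrediction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalRecord",
    "topk_accuracy",
    "ec_only_accuracy",
    "round_trip_accuracy",
    "class_breakdown",
    "breakdown_frame",
    "confusion_matrix_level1",
]


@dataclass(frozen=True)
class EvalRecord:
    """A query's ground truth and the model's ranked predictions.

    ``kind`` is ``"forward"`` (truth is a product) or ``"backward"`` (truth
    is a precursor set plus EC).  The ground truth must be canonicalised
    with the same canonicaliser as the predictions.
    """

    kind: str
    predictions: tuple[SingleStepPrediction, ...]
    truth_product: Optional[str] = None
    truth_precursors: tuple[str, ...] = ()
    truth_ec: Optional[ECNumber] = None

    def __post_init__(self) -> None:
        if self.kind not in ("forward", "backward"):
            raise ValueError(f"kind must be forward or backward, got {self.kind!r}")
        if self.kind == "forward" and self.truth_product is None:
            raise ValueError("forward records need a truth product")
        if self.kind == "backward" and not self.truth_precursors:
            raise ValueError("backward records need truth precursors")


def _matches(
    record: EvalRecord,
    pred: SingleStepPrediction,
    require_ec: bool,
    ignore_stereo: bool,
) -> bool:
    def norm(s: str) -> str:
        return strip_stereo(s) if ignore_stereo else s

    if record.kind == "forward":
        return pred.product is not None and norm(pred.product) == norm(
            record.truth_product
        )
    precursors_match = tuple(sorted(norm(p) for p in pred.precursors)) == tuple(
        sorted(norm(p) for p in record.truth_precursors)
    )
    if not require_ec:
        return precursors_match
    return precursors_match and pred.ec == record.truth_ec


def topk_accuracy(
    records: Sequence[EvalRecord],
    k: int,
    require_ec: bool = True,
    ignore_stereo: bool = False,
) -> float:
    """Fraction of records whose ground truth appears at rank <= k.

    Forward truth is the product; backward truth is the precursor set
    (order-insensitive) and, when ``require_ec``, the EC at the evaluation
    scheme.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("cannot compute accuracy over an empty record list")
    hits = 0
    for rec in records:
        if any(
            _matches(rec, p, require_ec, ignore_stereo) for p in rec.predictions[:k]
        ):
            hits += 1
    return hits / len(records)


def ec_only_accuracy(records: Sequence[EvalRecord], k: int) -> float:
    """Backward top-k accuracy counting only the predicted EC number.

    A prediction matches iff its EC equals the true EC, precursors ignored;
    always at least the full backward accuracy at equal k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("cannot compute accuracy over an empty record list")
    hits = 0
    for rec in records:
        if rec.kind != "backward":
            raise ValueError("ec_only_accuracy is defined for backward records")
        if any(p.ec == rec.truth_ec for p in rec.predictions[:k]):
            hits += 1
    return hits / len(records)


def round_trip_accuracy(
    backward_model: BackwardPredictor,
    forward_model: ForwardPredictor,
    products: Sequence[str],
    k: int,
) -> float:
    """Fraction of targets with a top-k backward proposal that round-trips.

    A proposal round-trips iff the forward model's rank-1 product on the
    proposed (precursors, EC) equals the target.  A model failure on a
    query counts the record incorrect and is logged.
    """
    if not products:
        raise ValueError("cannot compute round-trip accuracy over no products")
    hits = 0
    for target in products:
        try:
            proposals = backward_model.predict(BackwardQuery(product=target), k)
            ok = False
            for prop in proposals[:k]:
                forward = forward_model.predict(
                    ForwardQuery(reactants=prop.precursors, ec=prop.ec), 1
                )
                if forward and forward[0].product == target:
                    ok = True
                    break
            hits += ok
        except Exception as exc:  # noqa: BLE001 - contract: count incorrect, log
            logger.warning("model failure on target %s: %s", target, exc)
    return hits / len(products)


def class_breakdown(
    records: Sequence[EvalRecord],
    level: int = 1,
    ks: Sequence[int] = (1, 2, 3, 4, 5),
    require_ec: bool = True,
) -> dict[str, dict]:
    """Top-k accuracies within groups keyed by the truncated true EC.

    ``level`` 1 groups by enzyme class, 3 by EC level-3 subclass.  Returns
    ``{group: {"n": N, "topk": {k: acc}}}``.
    """
    if level not in (1, 3):
        raise ValueError("breakdown level must be 1 or 3")
    grouped: dict[str, list[EvalRecord]] = {}
    for rec in records:
        if rec.truth_ec is None:
            raise ValueError("class breakdown requires a true EC on every record")
        key = str(truncate_ec(rec.truth_ec, min(level, rec.truth_ec.level)))
        grouped.setdefault(key, []).append(rec)
    return {
        key: {
            "n": len(group),
            "topk": {k: topk_accuracy(group, k, require_ec=require_ec) for k in ks},
        }
        for key, group in sorted(grouped.items())
    }


def breakdown_frame(breakdown: dict[str, dict]) -> pd.DataFrame:
    """Tabular view of a class breakdown (one row per group)."""
    rows = []
    for key, entry in breakdown.items():
        row = {"group": key, "n": entry["n"]}
        row.update({f"top{k}": acc for k, acc in entry["topk"].items()})
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_matrix_level1(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """7x8 counts of true enzyme class vs rank-1 predicted class.

    Rows are true classes 1..7; columns are predicted classes 1..7 plus a
    ``"none"`` column for records with no prediction (or a prediction
    without an EC).  Row sums equal the per-class record counts.
    """
    classes = list(range(1, 8))
    matrix = pd.DataFrame(
        0, index=classes, columns=[*classes, "none"], dtype=int
    )
    for rec in records:
        if rec.kind != "backward":
            raise ValueError("the confusion matrix is defined for backward records")
        if rec.truth_ec is None:
            raise ValueError("confusion matrix requires a true EC on every record")
        true_class = rec.truth_ec.ec_class
        if rec.predictions and rec.predictions[0].ec is not None:
            matrix.loc[true_class, rec.predictions[0].ec.ec_class] += 1
        else:
            matrix.loc[true_class, "none"] += 1
    return matrix
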