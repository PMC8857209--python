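"""Single-step predictor contract, deterministic stub predictors, and the
EC-randomisation experiment.

The contract abstracts over any forward (substrates + EC -> product) or
backward (product -> precursors + EC) single-step model.  Two deterministic
stubs ship with the package so that evaluation metrics and the route planner
can be exercised end to end without a trained sequence model:

* :class:`LookupForwardPredictor` answers queries by exact lookup in a
  curated dataset, ranking candidate products by record multiplicity;
* :class:`TemplateBackwardPredictor` fires exact product-match disconnection
  rules ranked by declared priority.

External models (e.g. a trained seq2seq transformer) plug in through the
same ``predict(query, k)`` surface; :func:`validate_predictions` checks the
rank/confidence structure any adapter must satisfy.
"""

from __future__ import annotations

import logging
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Optional, Protocol, Sequence, runtime_checkable

from .chem_core import ECNumber
from .curation import CuratedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ForwardQuery",
    "BackwardQuery",
    "SingleStepPrediction",
    "ForwardPredictor",
    "BackwardPredictor",
    "validate_predictions",
    "LookupForwardPredictor",
    "TemplateRule",
    "TemplateBackwardPredictor",
    "randomize_ec",
]


@dataclass(frozen=True)
class ForwardQuery:
    """Substrates plus an optional EC number; asks for the product."""

    reactants: tuple[str, ...]
    ec: Optional[ECNumber] = None

    def __post_init__(self) -> None:
        if not self.reactants:
            raise ValueError("a forward query needs at least one reactant")


@dataclass(frozen=True)
class BackwardQuery:
    """A target product; asks for precursors and a catalysing EC."""

    product: str


@dataclass(frozen=True)
class SingleStepPrediction:
    """One ranked candidate from a single-step model.

    Forward candidates carry ``product``; backward candidates carry
    ``precursors`` and ``ec``.  Confidences live in [0, 1] and are
    non-increasing in rank within one query.
    """

    rank: int
    confidence: float
    product: Optional[str] = None
    precursors: tuple[str, ...] = ()
    ec: Optional[ECNumber] = None


@runtime_checkable
class ForwardPredictor(Protocol):
    def predict(self, query: ForwardQuery, k: int) -> list[SingleStepPrediction]: ...


@runtime_checkable
class BackwardPredictor(Protocol):
    def predict(self, query: BackwardQuery, k: int) -> list[SingleStepPrediction]: ...


def validate_predictions(preds: Sequence[SingleStepPrediction]) -> None:
    """Conformance check for predictor output (ranks 1..k, confidences
    in [0,1] and non-increasing).  Raises ``ValueError`` on violation."""
    for i, p in enumerate(preds):
        if p.rank != i + 1:
            raise ValueError(f"ranks must be 1..k without gaps; got {p.rank} at {i}")
        if not 0.0 <= p.confidence <= 1.0:
            raise ValueError(f"confidence {p.confidence} outside [0, 1]")
    for a, b in zip(preds, preds[1:]):
        if b.confidence > a.confidence + 1e-12:
            raise ValueError("confidences must be non-increasing in rank")


def _ec_key(ec: Optional[ECNumber]) -> str:
    return str(ec) if ec is not None else ""


class LookupForwardPredictor:
    """Exact-match forward stub over a curated dataset.

    Products matching (sorted reactants, EC) are ranked by multiplicity
    (provenance record count) then lexicographically; confidence is the
    normalised multiplicity.  Pure: repeated calls agree.
    """

    kind = "forward"

    def __init__(self, table: CuratedDataset, top_k: int = 10):
        self.top_k = top_k
        self._index: dict[tuple, Counter] = defaultdict(Counter)
        for rxn, prov in zip(table.records, table.provenance):
            key = (rxn.sorted_reactants(), _ec_key(rxn.ec))
            self._index[key][rxn.products[0]] += max(1, len(prov))

    def predict(self, query: ForwardQuery, k: int) -> list[SingleStepPrediction]:
        key = (tuple(sorted(query.reactants)), _ec_key(query.ec))
        counter = self._index.get(key)
        if not counter:
            return []
        total = sum(counter.values())
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return [
            SingleStepPrediction(rank=i + 1, confidence=count / total, product=prod)
            for i, (prod, count) in enumerate(ranked[: min(k, self.top_k)])
        ]


@dataclass(frozen=True)
class TemplateRule:
    """A deterministic disconnection rule: exact product -> (precursors, EC)."""

    product: str
    precursors: tuple[str, ...]
    ec: ECNumber
    priority: float = 1.0


class TemplateBackwardPredictor:
    """Rule-table backward stub; all applicable rules fire, ranked by
    priority (descending) with lexicographic precursor tie-break, confidence
    being the normalised priority."""

    kind = "backward"

    def __init__(self, rules: Sequence[TemplateRule], top_k: int = 10):
        self.top_k = top_k
        self._by_product: dict[str, list[TemplateRule]] = defaultdict(list)
        for rule in rules:
            self._by_product[rule.product].append(rule)

    def predict(self, query: BackwardQuery, k: int) -> list[SingleStepPrediction]:
        applicable = self._by_product.get(query.product, [])
        if not applicable:
            return []
        total = sum(r.priority for r in applicable)
        ranked = sorted(
            applicable, key=lambda r: (-r.priority, ".".join(sorted(r.precursors)))
        )
        return [
            SingleStepPrediction(
                rank=i + 1,
                confidence=rule.priority / total,
                precursors=tuple(sorted(rule.precursors)),
                ec=rule.ec,
            )
            for i, rule in enumerate(ranked[: min(k, self.top_k)])
        ]


def randomize_ec(
    test: CuratedDataset, mode: str, seed: int = 0
) -> CuratedDataset:
    """Replace each record's EC by one drawn from the test set's own ECs.

    ``within_class`` draws uniformly from ECs sharing the record's level-1
    class (excluding the record's own EC when an alternative exists; a
    singleton class leaves the record unchanged with a warning);
    ``across_class`` draws from ECs whose level-1 class differs.  Substrates
    and products are untouched, so the multiset of (reactants, product)
    pairs is preserved exactly.  Deterministic given the seed.
    """
    if mode not in ("within_class", "across_class"):
        raise ValueError(f"mode must be within_class or across_class, got {mode!r}")
    rng = random.Random(seed)

    ecs = sorted({r.ec for r in test.records if r.ec is not None})
    if any(r.ec is None for r in test.records):
        raise ValueError("every record must carry an EC number for randomisation")
    by_class: dict[int, list[ECNumber]] = defaultdict(list)
    for ec in ecs:
        by_class[ec.ec_class].append(ec)

    new_records = []
    for rxn in test.records:
        cls = rxn.ec.ec_class
        if mode == "within_class":
            pool = [e for e in by_class[cls] if e != rxn.ec]
            if not pool:
                logger.warning(
                    "class %d has no alternative EC for %s; record left unchanged",
                    cls,
                    rxn.ec,
                )
                new_records.append(rxn)
                continue
        else:
            pool = [e for c, group in sorted(by_class.items()) if c != cls for e in group]
            if not pool:
                raise ValueError(
                    "across_class randomisation needs ECs from at least two classes"
                )
        new_records.append(replace(rxn, ec=rng.choice(pool)))

    return CuratedDataset(
        scheme=test.scheme, records=tuple(new_records), provenance=test.provenance
    )
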