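"""Multi-step retrosynthetic route search over single-step models.

At each level the planner proposes disconnections for every unsolved leaf of
every partial route using the backward model, keeps only proposals that pass
the round-trip filter (the forward model's rank-1 product must regenerate the
parent molecule), scores each step by the forward confidence reweighted by
the synthetic complexity of the precursors, and prunes the resulting child
routes with beam search.  A branch terminates when all of its leaves are
commercially available (in the stock) or the depth limit is hit.

Step score:  combined = p_fwd * exp(-lambda * (mean(complexity) - 1))

with complexity on the 1-5 SCScore-style scale; at lambda = 0 the score is
the forward confidence alone.  A route's score is the product of its step
scores, so both are in [0, 1].  The complexity scorer is pluggable: the
default is a closed-form heuristic monotone in heavy-atom, ring and
stereocentre counts; a trained synthetic-complexity model can be dropped in
behind the same one-argument callable.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from rdkit import Chem

from .chem_core import ECNumber, SmilesParseError, canonicalize
from .predict import BackwardPredictor, BackwardQuery, ForwardPredictor, ForwardQuery

logger = logging.getLogger(__name__)

__all__ = [
    "Stock",
    "SynthesisStep",
    "Route",
    "PlannerConfig",
    "complexity_score",
    "score_step",
    "expand",
    "plan",
    "serialize_route",
    "parse_route",
]


@dataclass(frozen=True)
class Stock:
    """Commercially available molecules; membership is exact canonical
    string equality."""

    molecules: frozenset[str]

    @classmethod
    def from_smiles(cls, smiles: Iterable[str]) -> "Stock":
        return cls(frozenset(canonicalize(s) for s in smiles))

    @classmethod
    def from_file(cls, path) -> "Stock":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_smiles(s.strip() for s in lines if s.strip())

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.molecules

    def __len__(self) -> int:
        return len(self.molecules)


def complexity_score(smiles: str) -> float:
    """Heuristic synthetic-complexity proxy on the SCScore range [1, 5].

    Closed form, monotone in heavy-atom count, ring count and stereocentre
    count:

        1 + 0.04*(heavy_atoms - 1) + 0.35*rings + 0.25*stereocentres

    clamped to [1, 5].  A single-heavy-atom acyclic molecule scores exactly
    1.0 (the floor of the range).  Pluggable: any callable mapping SMILES to
    [1, 5] can replace it in the planner.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    rings = mol.GetRingInfo().NumRings()
    stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    score = 1.0 + 0.04 * (heavy - 1) + 0.35 * rings + 0.25 * stereo
    return min(5.0, max(1.0, score))


def score_step(
    backward_conf: float,
    forward_conf: float,
    precursor_complexities: Sequence[float],
    complexity_weight: float = 0.25,
) -> float:
    """Forward confidence reweighted by mean precursor complexity.

    ``combined = forward_conf * exp(-lambda * (mean(c) - 1))`` with
    complexities on [1, 5].  Monotone increasing in the forward confidence,
    monotone decreasing in the mean complexity; equal to the forward
    confidence when lambda is 0 or every precursor sits at the complexity
    floor.
    """
    if not 0.0 <= backward_conf <= 1.0 or not 0.0 <= forward_conf <= 1.0:
        raise ValueError("confidences must lie in [0, 1]")
    if complexity_weight < 0:
        raise ValueError("complexity weight must be non-negative")
    if not precursor_complexities:
        raise ValueError("at least one precursor complexity is required")
    if any(not 1.0 <= c <= 5.0 for c in precursor_complexities):
        raise ValueError("complexities must lie in [1, 5]")
    mean_c = sum(precursor_complexities) / len(precursor_complexities)
    return forward_conf * math.exp(-complexity_weight * (mean_c - 1.0))


@dataclass(frozen=True)
class SynthesisStep:
    """One retrosynthetic disconnection with its scoring components."""

    product: str
    precursors: tuple[str, ...]
    ec: Optional[ECNumber]
    backward_confidence: float
    forward_confidence: float
    complexities: tuple[float, ...]
    combined_score: float


@dataclass(frozen=True)
class PlannerConfig:
    beam_width: int = 10
    max_depth: int = 6
    expansions_per_node: int = 5
    complexity_weight: float = 0.25
    seed: int = 0
    #: cap on child combinations generated per partial route per level
    max_combinations: int = 1000

    def __post_init__(self) -> None:
        if self.beam_width < 1 or self.max_depth < 1 or self.expansions_per_node < 1:
            raise ValueError("beam_width, max_depth and expansions_per_node must be >= 1")
        if self.complexity_weight < 0:
            raise ValueError("complexity_weight must be non-negative")


@dataclass(frozen=True)
class Route:
    """A synthesis route: a tree of steps whose leaves should sit in stock.

    ``steps`` maps each intermediate product to the step that makes it; the
    tree is reconstructed from the target downwards.  ``solved`` means every
    leaf is in stock.
    """

    target: str
    steps: dict[str, SynthesisStep] = field(default_factory=dict)
    leaves: frozenset[str] = frozenset()
    route_score: float = 1.0
    depth: int = 0
    solved: bool = False

    def step_for(self, molecule: str) -> Optional[SynthesisStep]:
        return self.steps.get(molecule)


def expand(
    product: str,
    backward_model: BackwardPredictor,
    forward_model: ForwardPredictor,
    scorer: Callable[[str], float] = complexity_score,
    k: int = 5,
    complexity_weight: float = 0.25,
) -> list[SynthesisStep]:
    """Top-k backward proposals for one molecule, round-trip filtered.

    A proposal survives only if the forward model's rank-1 product on the
    proposed (precursors, EC) regenerates ``product``.  Survivors are scored
    and sorted by combined score (ties broken lexicographically on the
    serialised precursors).
    """
    try:
        proposals = backward_model.predict(BackwardQuery(product=product), k)
    except Exception as exc:  # noqa: BLE001 - contract: empty expansion, log
        logger.warning("backward model failed on %s: %s", product, exc)
        return []

    steps = []
    for prop in proposals:
        try:
            forward = forward_model.predict(
                ForwardQuery(reactants=prop.precursors, ec=prop.ec), 1
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("forward check failed on %s: %s", prop.precursors, exc)
            continue
        if not forward or forward[0].product != product:
            continue
        complexities = tuple(scorer(p) for p in prop.precursors)
        combined = score_step(
            prop.confidence, forward[0].confidence, complexities, complexity_weight
        )
        steps.append(
            SynthesisStep(
                product=product,
                precursors=prop.precursors,
                ec=prop.ec,
                backward_confidence=prop.confidence,
                forward_confidence=forward[0].confidence,
                complexities=complexities,
                combined_score=combined,
            )
        )
    steps.sort(key=lambda s: (-s.combined_score, ".".join(s.precursors)))
    return steps


@dataclass(frozen=True)
class _Partial:
    """A partial route during search: accepted steps plus open frontier."""

    steps: tuple[tuple[str, SynthesisStep], ...]
    # frontier: (molecule, ancestors on its path) for every unsolved leaf
    frontier: tuple[tuple[str, frozenset[str]], ...]
    score: float

    def key(self) -> tuple:
        return tuple(
            sorted((m, s.precursors, str(s.ec) if s.ec else "") for m, s in self.steps)
        )


def _finish(target: str, partial: _Partial, stock: Stock, depth: int) -> Route:
    steps = dict(partial.steps)
    leaves = set()

    def collect(mol: str) -> None:
        step = steps.get(mol)
        if step is None or mol in stock:
            leaves.add(mol)
            return
        for p in step.precursors:
            collect(p)

    collect(target)
    solved = all(m in stock for m in leaves)
    return Route(
        target=target,
        steps=steps,
        leaves=frozenset(leaves),
        route_score=partial.score,
        depth=depth,
        solved=solved,
    )


def plan(
    target: str,
    backward_model: BackwardPredictor,
    forward_model: ForwardPredictor,
    stock: Stock,
    cfg: PlannerConfig = PlannerConfig(),
    scorer: Callable[[str], float] = complexity_score,
) -> list[Route]:
    """Level-synchronous beam search for stock-terminated routes.

    At each depth every unsolved leaf of every beam candidate is expanded;
    child routes combine one surviving step per open leaf, are pruned to the
    top ``beam_width`` by route score (the product of step scores), and a
    branch is closed as solved when its frontier empties into the stock.
    Solved routes are returned best-first.  A molecule may not reappear on
    its own ancestor path (cycle guard).  Deterministic for deterministic
    models.
    """
    target = canonicalize(target)
    if len(stock) == 0:
        raise ValueError("stock must be non-empty")
    if target in stock:
        logger.info("target %s is already in stock; trivial route", target)
        return [
            Route(
                target=target,
                steps={},
                leaves=frozenset({target}),
                route_score=1.0,
                depth=0,
                solved=True,
            )
        ]

    solved: list[Route] = []
    beam: list[_Partial] = [
        _Partial(steps=(), frontier=((target, frozenset()),), score=1.0)
    ]

    for depth in range(1, cfg.max_depth + 1):
        children: list[_Partial] = []
        for partial in beam:
            options_per_leaf: list[list[SynthesisStep]] = []
            dead = False
            for mol, ancestors in partial.frontier:
                steps = expand(
                    mol,
                    backward_model,
                    forward_model,
                    scorer=scorer,
                    k=cfg.expansions_per_node,
                    complexity_weight=cfg.complexity_weight,
                )
                blocked = ancestors | {mol}
                steps = [
                    s for s in steps if not any(p in blocked for p in s.precursors)
                ]
                if not steps:
                    dead = True
                    break
                options_per_leaf.append(steps)
            if dead:
                continue

            combos = itertools.islice(
                itertools.product(*options_per_leaf), cfg.max_combinations
            )
            for chosen in combos:
                new_steps = dict(partial.steps)
                ok = True
                for (mol, _), step in zip(partial.frontier, chosen):
                    if mol in new_steps and new_steps[mol] != step:
                        ok = False
                        break
                    new_steps[mol] = step
                if not ok:
                    continue
                new_frontier = []
                for (mol, ancestors), step in zip(partial.frontier, chosen):
                    for p in step.precursors:
                        if p not in stock:
                            new_frontier.append((p, ancestors | {mol}))
                score = partial.score
                for step in chosen:
                    score *= step.combined_score
                child = _Partial(
                    steps=tuple(sorted(new_steps.items(), key=lambda kv: kv[0])),
                    frontier=tuple(
                        sorted(new_frontier, key=lambda f: (f[0], sorted(f[1])))
                    ),
                    score=score,
                )
                children.append(child)

        # dedupe identical step sets, keep best score
        unique: dict[tuple, _Partial] = {}
        for child in children:
            key = child.key()
            if key not in unique or child.score > unique[key].score:
                unique[key] = child

        next_beam: list[_Partial] = []
        for child in sorted(
            unique.values(), key=lambda c: (-c.score, c.key())
        ):
            if not child.frontier:
                solved.append(_finish(target, child, stock, depth))
            else:
                next_beam.append(child)
        beam = next_beam[: cfg.beam_width]
        if not beam:
            break

    solved.sort(key=lambda r: (-r.route_score, sorted(r.steps)))
    return solved


def _route_node(route: Route, molecule: str, stock_hint: frozenset[str]) -> dict:
    step = route.steps.get(molecule)
    node: dict = {"molecule": molecule}
    if step is None:
        node["in_stock"] = molecule in stock_hint or molecule in route.leaves
        node["children"] = []
        return node
    node["ec"] = str(step.ec) if step.ec else None
    node["backward_confidence"] = step.backward_confidence
    node["forward_confidence"] = step.forward_confidence
    node["complexities"] = list(step.complexities)
    node["combined_score"] = step.combined_score
    node["children"] = [
        _route_node(route, p, stock_hint) for p in step.precursors
    ]
    return node


def serialize_route(route: Route) -> str:
    """Nested JSON for a route; :func:`parse_route` is its inverse."""
    payload = {
        "target": route.target,
        "route_score": route.route_score,
        "depth": route.depth,
        "solved": route.solved,
        "tree": _route_node(route, route.target, frozenset()),
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def _collect_steps(node: dict, steps: dict[str, SynthesisStep]) -> None:
    children = node.get("children", [])
    if not children:
        return
    precursors = tuple(c["molecule"] for c in children)
    steps[node["molecule"]] = SynthesisStep(
        product=node["molecule"],
        precursors=precursors,
        ec=ECNumber.parse(node["ec"]) if node.get("ec") else None,
        backward_confidence=node["backward_confidence"],
        forward_confidence=node["forward_confidence"],
        complexities=tuple(node["complexities"]),
        combined_score=node["combined_score"],
    )
    for child in children:
        _collect_steps(child, steps)


def parse_route(text: str) -> Route:
    """Rebuild a :class:`Route` from its JSON serialisation."""
    payload = json.loads(text)
    steps: dict[str, SynthesisStep] = {}
    _collect_steps(payload["tree"], steps)

    leaves: set[str] = set()

    def walk(node: dict) -> None:
        if not node.get("children"):
            leaves.add(node["molecule"])
            return
        for child in node["children"]:
            walk(child)

    walk(payload["tree"])
    return Route(
        target=payload["target"],
        steps=steps,
        leaves=frozenset(leaves),
        route_score=payload["route_score"],
        depth=payload["depth"],
        solved=payload["solved"],
    )
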