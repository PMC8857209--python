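"""Deterministic synthetic data generation for desk-scale testing.

Real enzymatic reaction collections are merged from several databases and
arrive with cross-source duplicates, multi-product records polluted by
cofactors and tiny byproducts, and EC annotations of varying depth.  The
generator emulates exactly those conditions from a closed template grammar
(oxidation, transamination, ester hydrolysis, dehydration, isomerisation,
amide ligation and phosphorylation motifs over a small alcohol/acid/amine
alphabet, about twenty building blocks in total) so that brute-force oracles
stay fast and every curation rule is exercised.

Each template family carries a fixed EC level-3 path consistent with its
chemistry class (ester hydrolysis -> 3.1.1, transamination -> 2.6.1, ...)
purely as a label; level-4 serials are drawn per record so all four EC
levels and all seven classes appear.  No claim of biochemical accuracy is
made — the labels provide class structure for the metrics, not chemistry.

Alongside the data the generator emits a manifest with the expected curation
survivors per token scheme, computed from the clean (pre-injection) form of
each record, so tests never derive their expectations from the code under
test.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass

from .chem_core import ECNumber, EnzymaticReaction, canonicalize, format_reaction_smiles
from .curation import DEFAULT_BYPRODUCTS, DEFAULT_COENZYMES, CuratedDataset, RawRecord
from .predict import TemplateRule
from .retro_planner import Stock
from .tokenizer import SCHEMES, scheme_level

__all__ = ["FixtureSpec", "make_raw_records", "write_fixture_dir", "make_route_scenario"]

#: alkyl chains used as molecule cores; >= 3 carbons so every clean product
#: clears the heavy-atom-count >= 4 curation threshold
_CHAINS = ("CCC", "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CCC(C)C", "CCCC(C)C")
#: acyl roots for acids/esters/amides
_ACYLS = ("C", "CC", "CCC", "CCCC", "CC(C)")

_AMINE_DONOR = "NCC(=O)O"  # glycine-like amine donor
_KETO_BYPRODUCT = "O=CC(=O)O"  # glyoxylate-like keto acid
_DIPHOSPHATE = "OP(=O)(O)OP(=O)(O)O"

#: small molecules (heavy atoms < 4) injected as noise products; disjoint
#: from the default cofactor list so the injection rates stay independent
_SMALL_PRODUCTS = ("C=O", "CO", "CCO", "N", "CC")

_SOURCES = ("rhea", "brenda", "pathbank", "metanetx")


@dataclass(frozen=True)
class FixtureSpec:
    """Generation conditions for a synthetic raw-record corpus."""

    seed: int = 0
    n_reactions: int = 200
    #: proportions over EC classes 1..7; uniform by default
    class_mix: tuple[float, ...] = (1 / 7,) * 7
    cofactor_rate: float = 0.15
    small_product_rate: float = 0.10
    duplicate_rate: float = 0.10
    route_depth: int = 3
    sources: tuple[str, ...] = _SOURCES

    def __post_init__(self) -> None:
        if self.n_reactions <= 0:
            raise ValueError("n_reactions must be positive")
        if len(self.class_mix) != 7 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix needs 7 non-negative proportions")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for name in ("cofactor_rate", "small_product_rate", "duplicate_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if len(self.sources) < 2:
            raise ValueError("at least two sources are needed for duplicates")


def _template(ec_class: int, rng: random.Random) -> tuple[list[str], str, tuple[int, int, int]]:
    """One clean (reactants, product, EC level-3 path) draw for a class."""
    chain = rng.choice(_CHAINS)
    if ec_class == 1:  # alcohol oxidation
        return [f"O{chain}"], f"O={chain}", (1, 1, 1)
    if ec_class == 2:  # transamination of an aldehyde
        return [f"O={chain}", _AMINE_DONOR], f"N{chain}", (2, 6, 1)
    if ec_class == 3:  # ester hydrolysis
        acyl = rng.choice(_ACYLS)
        ester = f"{acyl}C(=O)O{chain}"
        return [ester, "O"], f"{acyl}C(=O)O", (3, 1, 1)
    if ec_class == 4:  # dehydration of a primary alcohol
        return [f"OC{chain}"], f"C={chain}", (4, 2, 1)
    if ec_class == 5:  # aldehyde/ketone isomerisation
        return [f"O=C{chain}"], f"CC(=O){chain[1:]}" if chain.startswith("C") else f"CC(=O){chain}", (5, 3, 1)
    if ec_class == 6:  # amide ligation
        acyl = rng.choice(_ACYLS)
        return [f"{acyl}C(=O)O", f"N{chain}"], f"{acyl}C(=O)N{chain}", (6, 3, 1)
    if ec_class == 7:  # phosphoryl transfer, labelled as the translocase class
        return [f"O{chain}", _DIPHOSPHATE], f"OP(=O)(O)O{chain}", (7, 1, 2)
    raise ValueError(f"EC class out of range: {ec_class}")


def make_raw_records(spec: FixtureSpec) -> tuple[list[RawRecord], dict]:
    """Generate raw records plus a ground-truth manifest.

    Duplicates (same reaction under a second source), cofactor products and
    heavy-atom-count-below-4 products are injected at the spec'd rates.  The
    manifest lists, per token scheme, the expected unique extended reaction
    SMILES after curation — derived from the clean single-product form of
    each record, not from the curation code.
    """
    rng = random.Random(spec.seed)
    cofactors = sorted(
        canonicalize(s) for s in (DEFAULT_COENZYMES | DEFAULT_BYPRODUCTS)
    )
    classes = list(range(1, 8))

    records: list[RawRecord] = []
    clean: list[EnzymaticReaction] = []
    for _ in range(spec.n_reactions):
        ec_class = rng.choices(classes, weights=spec.class_mix)[0]
        reactants, product, path = _template(ec_class, rng)
        serial = rng.randint(1, 9)
        ec = ECNumber((*path, serial))
        clean_rxn = EnzymaticReaction(
            reactants=tuple(sorted(canonicalize(r) for r in reactants)),
            products=(canonicalize(product),),
            ec=ec,
        )
        clean.append(clean_rxn)

        products = list(clean_rxn.products)
        if rng.random() < spec.cofactor_rate:
            products.append(rng.choice(cofactors))
        if rng.random() < spec.small_product_rate:
            products.append(canonicalize(rng.choice(_SMALL_PRODUCTS)))
        rng.shuffle(products)
        noisy = EnzymaticReaction(
            reactants=clean_rxn.reactants, products=tuple(products), ec=ec
        )
        source = rng.choice(spec.sources)
        records.append(RawRecord(rxn=noisy, source=source))
        if rng.random() < spec.duplicate_rate:
            other = rng.choice([s for s in spec.sources if s != source])
            records.append(RawRecord(rxn=noisy, source=other))

    expected: dict[str, list[str]] = {}
    for scheme in SCHEMES:
        level = scheme_level(scheme)
        seen = {}
        for rxn in clean:
            ec = rxn.ec.truncate(min(level, rxn.ec.level))
            key = format_reaction_smiles(
                EnzymaticReaction(
                    reactants=rxn.reactants, products=rxn.products, ec=ec
                )
            )
            seen[key] = True
        expected[scheme] = sorted(seen)

    manifest = {
        "seed": spec.seed,
        "n_raw_records": len(records),
        "n_clean_reactions": spec.n_reactions,
        "expected_unique": {s: len(v) for s, v in expected.items()},
        "expected_survivors": expected,
    }
    return records, manifest


def write_fixture_dir(spec: FixtureSpec, out_dir) -> dict:
    """Write the raw TSV, manifest JSON, stub rule files and stock list."""
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, manifest = make_raw_records(spec)
    pd.DataFrame(
        {
            "rxn_smiles": [format_reaction_smiles(r.rxn) for r in records],
            "ec": [str(r.rxn.ec) if r.rxn.ec else "" for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(out / "raw.tsv", sep="\t", index=False)

    target, rules, forward_table, stock, scenario = make_route_scenario(
        depth=spec.route_depth, branching=2, seed=spec.seed
    )
    (out / "stock.txt").write_text(
        "\n".join(sorted(stock.molecules)) + "\n", encoding="utf-8"
    )
    pd.DataFrame(
        {
            "product": [r.product for r in rules],
            "precursors": [".".join(r.precursors) for r in rules],
            "ec": [str(r.ec) for r in rules],
            "priority": [r.priority for r in rules],
        }
    ).to_csv(out / "backward_rules.tsv", sep="\t", index=False)
    forward_table.write_tsv(out / "forward_table.tsv")
    manifest["route_scenario"] = scenario
    manifest["route_target"] = target
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_route_scenario(depth: int, branching: int, seed: int = 0):
    """Construct a planted-route planner instance with matched stub models.

    Builds a reaction DAG with exactly one solvable route of ``depth`` steps
    from the target down to a stock set, plus ``branching - 1`` decoy
    disconnections per on-path molecule.  Decoys pass the round-trip filter
    (they have forward-table entries) but their precursor leaves are
    disjoint from the stock and have no further disconnections, so decoy
    branches can never terminate.

    Returns ``(target, backward_rules, forward_table, stock, manifest)``
    where the manifest records the planted route for oracle-free assertions.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")

    # on-path molecules: target = chain[0], ..., chain[depth] is in stock
    chain = [canonicalize("O" + "C" * (n + 3)) for n in range(depth + 1)]
    co_substrate = canonicalize("CC(=O)O")
    stock_molecules = {chain[depth], co_substrate}

    rules: list[TemplateRule] = []
    table_records: list[EnzymaticReaction] = []
    planted = []
    decoy_leaves: list[str] = []
    decoy_counter = 0
    for i in range(depth):
        ec = ECNumber((1, 1, 1, i + 1))
        precursors = tuple(sorted((chain[i + 1], co_substrate)))
        rules.append(
            TemplateRule(
                product=chain[i], precursors=precursors, ec=ec, priority=2.0
            )
        )
        table_records.append(
            EnzymaticReaction(reactants=precursors, products=(chain[i],), ec=ec)
        )
        planted.append(
            {"product": chain[i], "precursors": list(precursors), "ec": str(ec)}
        )
        for j in range(branching - 1):
            decoy_counter += 1
            decoy = canonicalize("N" + "C" * (decoy_counter + 3))
            decoy_leaves.append(decoy)
            dec_ec = ECNumber((2, 6, 1, j + 1))
            rules.append(
                TemplateRule(
                    product=chain[i], precursors=(decoy,), ec=dec_ec, priority=1.0
                )
            )
            table_records.append(
                EnzymaticReaction(reactants=(decoy,), products=(chain[i],), ec=dec_ec)
            )

    forward_table = CuratedDataset(
        scheme="EC4",
        records=tuple(table_records),
        provenance=tuple(("fixture",) for _ in table_records),
    )
    stock_obj = Stock(frozenset(stock_molecules))
    manifest = {
        "depth": depth,
        "branching": branching,
        "planted_route": planted,
        "decoy_leaves": sorted(decoy_leaves),
        "stock": sorted(stock_molecules),
    }
    return chain[0], rules, forward_table, stock_obj, manifest
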