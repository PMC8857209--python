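"""Shared fixtures: the hand-audited curation table, stub model pairs and
small evaluation corpora.  Everything is generated in-process; no data files."""

from __future__ import annotations

import pytest

from bioretro import (
    CuratedDataset,
    EnzymaticReaction,
    ECNumber,
    RawRecord,
    canonicalize,
    parse_reaction_smiles,
)

# ---------------------------------------------------------------------------
# Hand-audited 12-record curation fixture.
#
# Composition: 4 clean records (C1..C4), 2 cross-source duplicates of C1/C2,
# 1 cofactor-stripping case (phosphate byproduct), 1 combined self-product +
# small-product case (water on both sides, ethanol below 4 heavy atoms),
# 2 records that fail the validity rule (two persisting products; zero
# products after the small-product rule), and 2 records identical after EC
# truncation to level 3.  Expected survivors at EC3: 7.
# ---------------------------------------------------------------------------
TWELVE_RAW = [
    ("CCCO|1.1.1.1>>CCC=O", "rhea"),  # C1: clean oxidation
    ("OCCC|1.1.1.1>>O=CCC", "brenda"),  # duplicate of C1, rewritten SMILES
    ("O=CCCC.NCC(=O)O|2.6.1.1>>NCCCC", "rhea"),  # C2: clean transamination
    ("NCC(=O)O.O=CCCC|2.6.1.1>>CCCCN", "pathbank"),  # duplicate of C2, reordered
    ("CCC(=O)O.NCCC|6.3.1.1>>CCC(=O)NCCC", "metanetx"),  # C3: clean ligation
    ("O=CCC|5.3.1.1>>CC(C)=O", "rhea"),  # C4: clean isomerisation
    # rule 2: phosphate stripped from a two-product record
    ("CCCCCO.OP(=O)(O)OP(=O)(O)O|2.7.1.1>>OP(=O)(O)OCCCCC.OP(=O)(O)O", "brenda"),
    # rules 1+3: water is reactant and product; ethanol has 3 heavy atoms
    ("CCC(=O)OCC.O|3.1.1.1>>CCC(=O)O.CCO.O", "rhea"),
    # rule 4 failures
    ("CCCCCO|4.1.1.1>>CCCC=O.NCCCC", "metanetx"),  # two persisting products
    ("CCCO|1.1.1.5>>O", "rhea"),  # single product below 4 heavy atoms -> none left
    # identical after truncation to EC3
    ("CCCCO|1.1.1.2>>CCCC=O", "rhea"),
    ("CCCCO|1.1.1.3>>CCCC=O", "metanetx"),
]


def _survivor(reactants, ec, product):
    """Assemble an expected extended reaction SMILES by hand: canonical
    molecules, lexicographically sorted reactants, ASCII pipe."""
    mols = sorted(canonicalize(m) for m in reactants)
    return f"{'.'.join(mols)}|{ec}>>{canonicalize(product)}"


EXPECTED_SURVIVORS_EC3 = sorted(
    [
        _survivor(["CCCO"], "1.1.1", "CCC=O"),
        _survivor(["O=CCCC", "NCC(=O)O"], "2.6.1", "NCCCC"),
        _survivor(["CCC(=O)O", "NCCC"], "6.3.1", "CCC(=O)NCCC"),
        _survivor(["O=CCC"], "5.3.1", "CC(C)=O"),
        _survivor(["CCCCCO", "OP(=O)(O)OP(=O)(O)O"], "2.7.1", "OP(=O)(O)OCCCCC"),
        _survivor(["CCC(=O)OCC", "O"], "3.1.1", "CCC(=O)O"),
        _survivor(["CCCCO"], "1.1.1", "CCCC=O"),
    ]
)


@pytest.fixture(scope="session")
def twelve_records() -> list[RawRecord]:
    return [
        RawRecord(rxn=parse_reaction_smiles(text), source=source)
        for text, source in TWELVE_RAW
    ]


# ---------------------------------------------------------------------------
# A small curated dataset of invertible reactions for metric tests: ten
# distinct single-step reactions, each (substrate, acetate co-substrate) ->
# product with a class-i EC.
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def invertible_dataset() -> CuratedDataset:
    co = canonicalize("CC(=O)O")
    records = []
    for i in range(10):
        substrate = canonicalize("O" + "C" * (i + 3))
        product = canonicalize("N" + "C" * (i + 4))
        ec = ECNumber((i % 7 + 1, 1, 1, i + 1))
        records.append(
            EnzymaticReaction(
                reactants=tuple(sorted((substrate, co))),
                products=(product,),
                ec=ec,
            )
        )
    return CuratedDataset(
        scheme="EC4",
        records=tuple(records),
        provenance=tuple(("test",) for _ in records),
    )
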