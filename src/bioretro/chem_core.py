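"""Molecule/reaction data model and the enzymatic reaction SMILES grammar.

An enzymatic reaction SMILES extends an ordinary reaction SMILES with an
Enzyme Commission (EC) number annotation on the reactant side, e.g.
``CC(C)CO|1.1.1>>CC(C)C=O``.  The EC field is delimited from the reactant
SMILES by a pipe character; both the ASCII ``|`` and the typographic divides
character (U+2223) are accepted on input, and ASCII is always emitted.

All molecules are stored in a single fixed canonical form (RDKit canonical
isomeric SMILES) so that identity, deduplication and stock-membership checks
reduce to exact string equality.  Stereochemistry is preserved verbatim; no
isomeric information is ever stripped implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "SmilesParseError",
    "ReactionParseError",
    "canonicalize",
    "strip_stereo",
    "heavy_atom_count",
    "ECNumber",
    "truncate_ec",
    "EnzymaticReaction",
    "parse_reaction_smiles",
    "format_reaction_smiles",
    "fold_reagents",
]

#: EC field delimiters accepted on input.  U+2223 (DIVIDES) shows up in
#: typeset text; ASCII "|" is what files should contain and what we emit.
EC_DELIMITERS = ("|", "∣")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed as a molecule."""


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES is structurally malformed.

    Carries the offending text and, when known, the character position.
    """

    def __init__(self, message: str, text: str = "", position: Optional[int] = None):
        self.text = text
        self.position = position
        if position is not None:
            message = f"{message} (at position {position} in {text!r})"
        elif text:
            message = f"{message} (in {text!r})"
        super().__init__(message)


def canonicalize(smiles: str) -> str:
    """Return the fixed canonical SMILES of a molecule.

    Idempotent: canonicalising a canonical string returns it unchanged.
    Raises :class:`SmilesParseError` naming the offending input otherwise.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with all stereochemical information removed."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


@dataclass(frozen=True, order=True)
class ECNumber:
    """Hierarchical Enzyme Commission identifier with 1-4 levels.

    Level 1 is the enzyme class (1 oxidoreductases, 2 transferases,
    3 hydrolases, 4 lyases, 5 isomerases, 6 ligases, 7 translocases);
    deeper levels refine the catalysed chemistry.  Levels are contiguous
    from level 1 — a truncated EC like ``5.4.99`` is valid, a gapped one
    is not representable.
    """

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= 4:
            raise ValueError(f"EC number must have 1-4 levels, got {self.levels!r}")
        if not 1 <= self.levels[0] <= 7:
            raise ValueError(
                f"EC class (level 1) must be in 1..7, got {self.levels[0]}"
            )
        if any(not isinstance(x, int) or x < 1 for x in self.levels):
            raise ValueError(f"EC levels must be positive integers, got {self.levels!r}")

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        fields = text.strip().split(".")
        try:
            levels = tuple(int(f) for f in fields)
        except ValueError:
            raise ValueError(f"malformed EC number: {text!r}") from None
        return cls(levels)

    @property
    def level(self) -> int:
        """Number of levels present (1-4)."""
        return len(self.levels)

    @property
    def ec_class(self) -> int:
        """The level-1 enzyme class, 1..7."""
        return self.levels[0]

    def truncate(self, level: int) -> Optional["ECNumber"]:
        """Keep the first ``level`` fields; level 0 yields ``None``.

        Requesting more levels than are present is an error — levels are
        never invented by padding.
        """
        if not 0 <= level <= 4:
            raise ValueError(f"truncation level must be in 0..4, got {level}")
        if level == 0:
            return None
        if level > len(self.levels):
            raise ValueError(
                f"cannot truncate EC {self} to {level} levels: only "
                f"{len(self.levels)} present"
            )
        return ECNumber(self.levels[:level])

    def __str__(self) -> str:
        return ".".join(str(x) for x in self.levels)


def truncate_ec(ec: Optional[ECNumber], level: int) -> Optional[ECNumber]:
    """Functional form of :meth:`ECNumber.truncate`; absent EC stays absent."""
    if ec is None:
        if level == 0:
            return None
        raise ValueError("cannot truncate an absent EC number to a positive level")
    return ec.truncate(level)


@dataclass(frozen=True)
class EnzymaticReaction:
    """A reaction record: reactants, optional reagents, optional EC, products.

    All molecule fields hold canonical SMILES.  When ``ec`` is absent the
    record is a plain reaction SMILES.  ``source`` is a free-text provenance
    tag (e.g. the database the record came from).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    reagents: tuple[str, ...] = ()
    ec: Optional[ECNumber] = None
    source: str = ""

    def sorted_reactants(self) -> tuple[str, ...]:
        return tuple(sorted(self.reactants))


def _split_molecules(part: str, text: str) -> tuple[str, ...]:
    if not part:
        return ()
    return tuple(canonicalize(m) for m in part.split("."))


def parse_reaction_smiles(text: str, source: str = "") -> EnzymaticReaction:
    """Parse a (possibly enzymatic) reaction SMILES.

    Accepts the two-part ``reactants>>products`` and three-part
    ``reactants>agents>products`` grammars, with an optional EC suffix on
    the reactant side (``A|1.1.1>>B``).  Molecules are canonicalised.
    """
    s = text.strip()
    if not s:
        raise ReactionParseError("empty reaction SMILES", text, 0)
    parts = s.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'r>>p' or 'r>agents>p', found {len(parts) - 1} '>' characters",
            s,
            s.find(">") if ">" in s else len(s),
        )
    left, middle, right = parts

    ec: Optional[ECNumber] = None
    for delim in EC_DELIMITERS:
        if delim in left:
            reactant_part, _, ec_text = left.partition(delim)
            if any(d in ec_text for d in EC_DELIMITERS):
                raise ReactionParseError(
                    "multiple EC delimiters on reactant side", s, s.index(delim)
                )
            try:
                ec = ECNumber.parse(ec_text)
            except ValueError as exc:
                raise ReactionParseError(
                    f"malformed EC field: {exc}", s, s.index(delim) + 1
                ) from None
            left = reactant_part
            break

    return EnzymaticReaction(
        reactants=_split_molecules(left, s),
        reagents=_split_molecules(middle, s),
        products=_split_molecules(right, s),
        ec=ec,
        source=source,
    )


def format_reaction_smiles(rxn: EnzymaticReaction) -> str:
    """Serialise a reaction; inverse of :func:`parse_reaction_smiles`.

    The EC field, when present, is emitted with the ASCII pipe.
    """
    left = ".".join(rxn.reactants)
    if rxn.ec is not None:
        left = f"{left}|{rxn.ec}"
    right = ".".join(rxn.products)
    if rxn.reagents:
        return f"{left}>{'.'.join(rxn.reagents)}>{right}"
    return f"{left}>>{right}"


def fold_reagents(rxn: EnzymaticReaction) -> EnzymaticReaction:
    """Move reagents onto the reactant side (two-part enzymatic form).

    The enzymatic grammar ``A|EC>>B`` has no agents field, so three-part
    records are folded before tokenisation or curation.
    """
    if not rxn.reagents:
        return rxn
    return replace(rxn, reactants=rxn.reactants + rxn.reagents, reagents=())
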