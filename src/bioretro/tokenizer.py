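"""Token-level encoding of enzymatic reaction SMILES for sequence models.

Molecular text is split with the standard atom-level reaction-SMILES regex
(bracket atoms, two-letter organic-subset halogens and ``%nn`` ring closures
kept whole).  EC numbers are emitted as one bracketed token per hierarchy
level with a letter prefix — ``v`` for level 1, ``u`` for level 2, ``t`` for
level 3 and ``s`` for level 4 — because bare digits already denote ring
closures in SMILES.  Each token carries the cumulative path of its level
(``[u5.4]``, not ``[u4]``) so tokens are unique per branch of the hierarchy
and a model can exploit the hierarchical structure.

The reaction arrow ``>>`` is emitted as two ``>`` tokens; seq2seq file
writers split source from target at the arrow, so the arrow itself never
appears inside one side of a training pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .chem_core import EC_DELIMITERS, ECNumber

__all__ = [
    "SCHEMES",
    "scheme_level",
    "TokenizationError",
    "TokenSequence",
    "tokenize_molecular",
    "tokenize_ec",
    "tokenize_enzymatic",
    "detokenize",
    "write_src_tgt",
]

SCHEMES = ("EC0", "EC1", "EC2", "EC3", "EC4")

#: level index -> EC token prefix
EC_PREFIXES = "vuts"

# Atom-level SMILES tokenisation (bracket atoms atomic, Cl/Br whole,
# %nn ring closures whole, single '>' per arrow half).
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|B|C|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)

EC_TOKEN_RE = re.compile(r"^\[([vuts])(\d+(?:\.\d+)*)\]$")


class TokenizationError(ValueError):
    """Raised on characters outside the SMILES alphabet or malformed tokens."""


def scheme_level(scheme: str) -> int:
    """EC depth of a token scheme name, e.g. ``"EC3" -> 3``."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown token scheme {scheme!r}; expected one of {SCHEMES}")
    return int(scheme[2])


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list together with the EC scheme it was produced under."""

    tokens: tuple[str, ...]
    scheme: str = "EC0"

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_molecular(text: str) -> list[str]:
    """Split molecular reaction-SMILES text into atom-level tokens.

    The concatenation of the returned tokens reproduces the input exactly;
    any residue outside the SMILES alphabet is an error.
    """
    tokens = SMILES_TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        residue = SMILES_TOKEN_RE.sub("", text)
        raise TokenizationError(
            f"characters outside the SMILES alphabet in {text!r}: {residue!r}"
        )
    return tokens


def tokenize_ec(ec: Optional[ECNumber], scheme: str) -> list[str]:
    """One bracketed token per EC level, cumulative-path surface form.

    The EC must already be truncated to the scheme's depth; scheme ``EC0``
    with a present EC is an error (truncate first).
    """
    level = scheme_level(scheme)
    if ec is None:
        return []
    if level == 0:
        raise TokenizationError(
            "scheme EC0 admits no EC tokens; truncate the EC to level 0 first"
        )
    if ec.level != level:
        raise TokenizationError(
            f"EC {ec} has {ec.level} levels but scheme {scheme} requires {level}; "
            "truncate first"
        )
    return [
        f"[{EC_PREFIXES[i]}{'.'.join(str(x) for x in ec.levels[: i + 1])}]"
        for i in range(ec.level)
    ]


def _split_enzymatic_text(text: str) -> tuple[str, Optional[str], str]:
    """Split ``A|ec>>B`` into (reactant text, ec text or None, product text)."""
    if ">>" not in text:
        raise TokenizationError(f"expected a '>>' arrow in {text!r}")
    left, _, right = text.partition(">>")
    if ">" in left or ">" in right:
        raise TokenizationError(
            f"three-part reaction SMILES {text!r}: fold agents into reactants first"
        )
    ec_text: Optional[str] = None
    for delim in EC_DELIMITERS:
        if delim in left:
            left, _, ec_text = left.partition(delim)
            break
    return left, ec_text, right


def tokenize_enzymatic(text: str, scheme: str) -> TokenSequence:
    """Tokenise a two-part enzymatic reaction SMILES under a scheme.

    Token order: reactant tokens, EC tokens, two ``>`` tokens, product
    tokens.  The EC depth in the text must match the scheme (absent for
    EC0).  Joining the tokens reproduces the ASCII-normalised source text.
    """
    level = scheme_level(scheme)
    left, ec_text, right = _split_enzymatic_text(text.strip())
    ec = ECNumber.parse(ec_text) if ec_text is not None else None
    if level == 0 and ec is not None:
        raise TokenizationError(f"scheme EC0 forbids an EC field, found {ec}")
    if level > 0 and ec is None:
        raise TokenizationError(f"scheme {scheme} requires an EC field in {text!r}")
    tokens = (
        tokenize_molecular(left)
        + tokenize_ec(ec, scheme)
        + [">", ">"]
        + tokenize_molecular(right)
    )
    return TokenSequence(tuple(tokens), scheme)


def is_ec_token(token: str) -> bool:
    return EC_TOKEN_RE.match(token) is not None


def detokenize(seq: TokenSequence | Iterable[str]) -> str:
    """Exact inverse of the tokenisers.

    EC tokens must form one contiguous run; the deepest token of the run
    determines the emitted ``|x.y.z`` field.  Detokenisation strips the
    single spaces used in token files (callers pass token lists here).
    """
    tokens = tuple(seq.tokens if isinstance(seq, TokenSequence) else seq)
    if not tokens:
        raise TokenizationError("cannot detokenize an empty token sequence")

    ec_positions = [i for i, t in enumerate(tokens) if is_ec_token(t)]
    for t in tokens:
        if t.startswith("[") and not t.endswith("]"):
            raise TokenizationError(f"malformed bracket token {t!r}")
    if not ec_positions:
        return "".join(tokens)

    first, last = ec_positions[0], ec_positions[-1]
    if ec_positions != list(range(first, last + 1)):
        raise TokenizationError("EC tokens must be contiguous")
    run = tokens[first : last + 1]
    paths = []
    for i, tok in enumerate(run):
        m = EC_TOKEN_RE.match(tok)
        if m.group(1) != EC_PREFIXES[i]:
            raise TokenizationError(
                f"EC token {tok!r} has prefix {m.group(1)!r}, expected "
                f"{EC_PREFIXES[i]!r} at level {i + 1}"
            )
        paths.append(m.group(2))
    for shallow, deep in zip(paths, paths[1:]):
        if not deep.startswith(shallow + "."):
            raise TokenizationError(
                f"inconsistent EC token path: {deep!r} does not extend {shallow!r}"
            )
    return "".join(tokens[:first]) + "|" + paths[-1] + "".join(tokens[last + 1 :])


def write_src_tgt(
    reactions: Iterable[str], scheme: str, src_path, tgt_path
) -> int:
    """Write the standard seq2seq token-file pair for a reaction corpus.

    Each src line holds the space-joined reactant + EC tokens, each tgt line
    the product tokens; the arrow is the line split itself.  Returns the
    number of lines written.
    """
    n = 0
    with open(src_path, "w", encoding="utf-8") as src, open(
        tgt_path, "w", encoding="utf-8"
    ) as tgt:
        for text in reactions:
            tokens = tokenize_enzymatic(text, scheme).tokens
            arrow = tokens.index(">")
            src.write(" ".join(tokens[:arrow]) + "\n")
            tgt.write(" ".join(tokens[arrow + 2 :]) + "\n")
            n += 1
    return n
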