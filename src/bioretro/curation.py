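"""Enzymatic reaction dataset construction.

The pipeline mirrors how public biochemical reaction collections (Rhea,
BRENDA, PathBank, MetaNetX exports) are merged into a clean single-product
reaction-EC dataset:

1. remove products that also occur as reactants in the same reaction;
2. in reactions with more than one product, remove known co-enzymes and
   common byproducts from the product side;
3. remove products with a heavy-atom count below 4;
4. keep only reactions with exactly one product and at least one reactant.

The surviving records are truncated to the target EC token scheme
(EC0..EC4) and deduplicated on their canonical extended reaction SMILES
(lexicographically sorted reactants + EC + product), merging provenance.
Truncating EC levels can only merge records, so unique-record counts are
monotone non-decreasing in the scheme depth.

Splitting is product-disjoint: records are grouped by product and whole
groups are assigned greedily (largest group first, to the split furthest
below its target size), so no product molecule ever appears in more than
one of train/validation/test.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .chem_core import (
    ECNumber,
    EnzymaticReaction,
    SmilesParseError,
    ReactionParseError,
    canonicalize,
    fold_reagents,
    format_reaction_smiles,
    heavy_atom_count,
    parse_reaction_smiles,
    truncate_ec,
)
from .tokenizer import scheme_level

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecord",
    "CofactorConfig",
    "CuratedDataset",
    "SplitSpec",
    "MultitaskWeights",
    "rule1_remove_self_products",
    "rule2_strip_cofactors",
    "rule3_remove_small_products",
    "rule4_validity_filter",
    "curate",
    "read_raw_tsv",
    "product_disjoint_split",
    "prepare_multitask_corpus",
    "emit_training_config",
    "read_training_config",
    "DEFAULT_TRAINING_CONFIG",
]

#: Ubiquitous co-enzymes and byproducts stripped from multi-product records.
#: Fully overridable via :meth:`CofactorConfig.from_file`.
DEFAULT_COENZYMES = {
    # NAD+ / NADH
    "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)c1",
    "NC(=O)C1=CN(C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)C=CC1",
    # NADP+ / NADPH
    "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)C(O)C2O)c1",
    "NC(=O)C1=CN(C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)C(O)C2O)C=CC1",
    # ATP / ADP / AMP
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O",
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O",
    # Coenzyme A
    "CC(C)(COP(=O)(O)OP(=O)(O)OCC1OC(n2cnc3c(N)ncnc32)C(O)C1OP(=O)(O)O)C(O)C(=O)NCCC(=O)NCCS",
}

DEFAULT_BYPRODUCTS = {
    "O",  # water
    "[H+]",
    "O=C=O",  # carbon dioxide
    "O=O",  # dioxygen
    "OP(=O)(O)O",  # phosphate
    "OP(=O)(O)OP(=O)(O)O",  # diphosphate
}


@dataclass(frozen=True)
class RawRecord:
    """A pre-curation reaction with its provenance source tag."""

    rxn: EnzymaticReaction
    source: str

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("RawRecord source must be non-empty")


@dataclass(frozen=True)
class CofactorConfig:
    """Canonicalised sets of co-enzymes and common byproducts."""

    coenzymes: frozenset[str]
    byproducts: frozenset[str]

    @classmethod
    def default(cls) -> "CofactorConfig":
        return cls(
            coenzymes=frozenset(canonicalize(s) for s in DEFAULT_COENZYMES),
            byproducts=frozenset(canonicalize(s) for s in DEFAULT_BYPRODUCTS),
        )

    @classmethod
    def from_file(cls, path) -> "CofactorConfig":
        """Read one SMILES per line ('#' comments allowed); all entries are
        treated as strippable byproducts."""
        entries = set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                entries.add(canonicalize(line))
        return cls(coenzymes=frozenset(), byproducts=frozenset(entries))

    @property
    def all_molecules(self) -> frozenset[str]:
        return self.coenzymes | self.byproducts


def rule1_remove_self_products(rxn: EnzymaticReaction) -> EnzymaticReaction:
    """Drop products that also occur among the reactants."""
    reactant_set = set(rxn.reactants)
    return replace(
        rxn, products=tuple(p for p in rxn.products if p not in reactant_set)
    )


def rule2_strip_cofactors(
    rxn: EnzymaticReaction, cfg: CofactorConfig
) -> EnzymaticReaction:
    """Strip known co-enzymes/byproducts from the product side.

    Applies only to reactions that exceed one product at entry (the gate is
    evaluated before this rule's own removals); the reactant side is never
    touched.
    """
    if len(rxn.products) <= 1:
        return rxn
    listed = cfg.all_molecules
    return replace(rxn, products=tuple(p for p in rxn.products if p not in listed))


def rule3_remove_small_products(rxn: EnzymaticReaction) -> EnzymaticReaction:
    """Drop products with fewer than 4 heavy atoms."""
    return replace(
        rxn, products=tuple(p for p in rxn.products if heavy_atom_count(p) >= 4)
    )


def rule4_validity_filter(rxn: EnzymaticReaction) -> bool:
    """Keep only reactions with exactly one product and >= 1 reactant."""
    return len(rxn.products) == 1 and len(rxn.reactants) >= 1


@dataclass(frozen=True)
class CuratedDataset:
    """Deduplicated single-product reaction records at one token scheme.

    ``provenance[i]`` is the multiset (tuple) of source tags whose raw
    records collapsed into ``records[i]``.
    """

    scheme: str
    records: tuple[EnzymaticReaction, ...]
    provenance: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.provenance):
            raise ValueError("records and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.records)

    def extended_smiles(self) -> list[str]:
        return [format_reaction_smiles(r) for r in self.records]

    def products(self) -> set[str]:
        return {r.products[0] for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rxn_smiles": self.extended_smiles(),
                "ec": [str(r.ec) if r.ec else "" for r in self.records],
                "sources": [";".join(p) for p in self.provenance],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, scheme: str) -> "CuratedDataset":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records, provenance = [], []
        for _, row in df.iterrows():
            rxn = parse_reaction_smiles(row["rxn_smiles"])
            records.append(rxn)
            provenance.append(tuple(row.get("sources", "").split(";")))
        return cls(scheme=scheme, records=tuple(records), provenance=tuple(provenance))


def _dedup_key(rxn: EnzymaticReaction) -> tuple:
    return (rxn.sorted_reactants(), str(rxn.ec) if rxn.ec else "", rxn.products[0])


def curate(
    records: Iterable[RawRecord],
    cfg: Optional[CofactorConfig] = None,
    scheme: str = "EC3",
) -> CuratedDataset:
    """Run the four filter rules, truncate ECs to the scheme, deduplicate.

    Records whose EC carries fewer levels than the scheme requests keep the
    levels they have (levels are never invented).  Unparseable inputs are
    the caller's concern: ``records`` holds already-parsed reactions; use
    :func:`read_raw_tsv` for text input with skip-and-log semantics.
    """
    if cfg is None:
        cfg = CofactorConfig.default()
    level = scheme_level(scheme)

    keyed: dict[tuple, EnzymaticReaction] = {}
    prov: dict[tuple, list[str]] = {}
    for rec in records:
        rxn = fold_reagents(rec.rxn)
        rxn = rule1_remove_self_products(rxn)
        rxn = rule2_strip_cofactors(rxn, cfg)
        rxn = rule3_remove_small_products(rxn)
        if not rule4_validity_filter(rxn):
            continue
        ec = truncate_ec(rxn.ec, min(level, rxn.ec.level)) if rxn.ec else None
        rxn = replace(rxn, reactants=rxn.sorted_reactants(), ec=ec, source="")
        key = _dedup_key(rxn)
        if key not in keyed:
            keyed[key] = rxn
            prov[key] = []
        prov[key].append(rec.source)

    keys = list(keyed)
    return CuratedDataset(
        scheme=scheme,
        records=tuple(keyed[k] for k in keys),
        provenance=tuple(tuple(prov[k]) for k in keys),
    )


def read_raw_tsv(path) -> tuple[list[RawRecord], int]:
    """Read a raw reaction table (columns rxn_smiles, ec, source).

    The EC may be embedded in the reaction SMILES or given in the ``ec``
    column.  Unparseable rows are logged and skipped, never silently
    dropped; returns (records, number skipped).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "rxn_smiles" not in df.columns or "source" not in df.columns:
        raise ValueError("raw TSV requires columns: rxn_smiles, ec, source")
    records: list[RawRecord] = []
    skipped = 0
    for i, row in df.iterrows():
        try:
            rxn = parse_reaction_smiles(row["rxn_smiles"])
            ec_text = row.get("ec", "").strip()
            if ec_text:
                if rxn.ec is not None and str(rxn.ec) != ec_text:
                    raise ReactionParseError(
                        f"EC column {ec_text!r} contradicts embedded EC {rxn.ec}"
                    )
                rxn = replace(rxn, ec=ECNumber.parse(ec_text))
            records.append(RawRecord(rxn=rxn, source=row["source"]))
        except (SmilesParseError, ReactionParseError, ValueError) as exc:
            skipped += 1
            logger.warning("skipping row %d: %s", i, exc)
    if skipped:
        logger.info("skipped %d unparseable rows out of %d", skipped, len(df))
    return records, skipped


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 0.90/0.05/0.05) and seed."""

    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(not 0 < f < 1 for f in self.fractions):
            raise ValueError("each split fraction must be in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def product_disjoint_split(
    ds: CuratedDataset, spec: SplitSpec = SplitSpec()
) -> tuple[CuratedDataset, CuratedDataset, CuratedDataset]:
    """Partition a dataset so no product occurs in more than one split.

    Records are grouped by canonical product; groups are assigned whole,
    largest first, to the split with the largest remaining deficit against
    its target record count (ties between equally-sized groups are broken
    by a seeded shuffle, ties between splits by train < valid < test
    order).  Deterministic given (dataset, seed).
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    groups: dict[str, list[int]] = {}
    for i, rxn in enumerate(ds.records):
        groups.setdefault(rxn.products[0], []).append(i)
    if len(groups) < 3:
        raise ValueError(
            f"need at least 3 distinct products to form 3 splits, got {len(groups)}"
        )

    rng = random.Random(spec.seed)
    order = sorted(groups)
    rng.shuffle(order)
    order.sort(key=lambda p: -len(groups[p]))  # stable: keeps shuffled tie order

    targets = [f * len(ds) for f in spec.fractions]
    counts = [0, 0, 0]
    assigned: list[list[int]] = [[], [], []]
    for product in order:
        deficits = [targets[j] - counts[j] for j in range(3)]
        j = max(range(3), key=lambda s: (deficits[s], -s))
        assigned[j].extend(groups[product])
        counts[j] += len(groups[product])

    def subset(idx: list[int]) -> CuratedDataset:
        idx = sorted(idx)
        return CuratedDataset(
            scheme=ds.scheme,
            records=tuple(ds.records[i] for i in idx),
            provenance=tuple(ds.provenance[i] for i in idx),
        )

    return subset(assigned[0]), subset(assigned[1]), subset(assigned[2])


@dataclass(frozen=True)
class MultitaskWeights:
    """Per-corpus positive integer sampling weights (default uspto:9, ecreact:1)."""

    weights: dict[str, int] = field(default_factory=lambda: {"uspto": 9, "ecreact": 1})

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("at least one corpus weight is required")
        for name, w in self.weights.items():
            if not isinstance(w, int) or w <= 0:
                raise ValueError(f"weight for {name!r} must be a positive integer")


def _count_lines(path) -> int:
    with open(path, "r", encoding="utf-8") as fh:
        return sum(1 for _ in fh)


def prepare_multitask_corpus(
    corpora: dict[str, tuple[str, str]],
    weights: MultitaskWeights,
    out_dir,
    sample_lines: int = 0,
    seed: int = 0,
) -> dict:
    """Declare per-corpus sampling weights; optionally materialise a sample.

    ``corpora`` maps a name to an (src, tgt) token-file pair with equal line
    counts.  The manifest (written as ``manifest.yaml``) records paths,
    weights and line counts for weighted-corpus trainers.  When
    ``sample_lines`` > 0, an interleaved sample is drawn in which corpus i
    contributes each line independently with probability w_i / sum(w).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(weights.weights) - set(corpora)
    if unknown:
        raise ValueError(f"weights given for unknown corpora: {sorted(unknown)}")

    manifest: dict = {"corpora": {}, "sample": None}
    lines: dict[str, tuple[list[str], list[str]]] = {}
    for name, (src_path, tgt_path) in corpora.items():
        n_src, n_tgt = _count_lines(src_path), _count_lines(tgt_path)
        if n_src != n_tgt:
            raise ValueError(
                f"corpus {name!r}: src has {n_src} lines but tgt has {n_tgt}"
            )
        manifest["corpora"][name] = {
            "src": str(src_path),
            "tgt": str(tgt_path),
            "weight": weights.weights.get(name, 1),
            "lines": n_src,
        }

    if sample_lines > 0:
        rng = random.Random(seed)
        names = sorted(corpora)
        w = [weights.weights.get(n, 1) for n in names]
        for name in names:
            src_path, tgt_path = corpora[name]
            with open(src_path, encoding="utf-8") as fh:
                src = fh.read().splitlines()
            with open(tgt_path, encoding="utf-8") as fh:
                tgt = fh.read().splitlines()
            lines[name] = (src, tgt)
        counts = {n: 0 for n in names}
        with open(out_dir / "sample.src", "w", encoding="utf-8") as s_out, open(
            out_dir / "sample.tgt", "w", encoding="utf-8"
        ) as t_out:
            for _ in range(sample_lines):
                name = rng.choices(names, weights=w)[0]
                src, tgt = lines[name]
                i = rng.randrange(len(src))
                s_out.write(src[i] + "\n")
                t_out.write(tgt[i] + "\n")
                counts[name] += 1
        manifest["sample"] = {
            "lines": sample_lines,
            "seed": seed,
            "counts": counts,
            "src": str(out_dir / "sample.src"),
            "tgt": str(out_dir / "sample.tgt"),
        }

    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


#: Published transformer hyper-parameters for external trainers; this
#: toolkit itself never trains a model.
DEFAULT_TRAINING_CONFIG = {
    "encoder_type": "transformer",
    "decoder_type": "transformer",
    "layers": 6,
    "word_vec_size": 512,
    "rnn_size": 512,
    "accum_count": 8,
    "max_grad_norm": 0.0,
    "optim": "adam",
    "adam_beta1": 0.9,
    "adam_beta2": 0.998,
    "batch_size": 4096,
    "batch_type": "tokens",
    "normalization": "tokens",
    "learning_rate": 2.0,
    "decay_method": "noam",
    "dropout": 0.1,
    "label_smoothing": 0.1,
    "param_init": 0,
    "position_encoding": True,
}


def emit_training_config(path=None, **overrides) -> dict:
    """Write/return the training-config descriptor, with user overrides."""
    config = dict(DEFAULT_TRAINING_CONFIG)
    config.update(overrides)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
    return config


def read_training_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
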