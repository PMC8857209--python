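# bioretro

A toolkit for **biocatalysed synthesis planning**: it implements the data
model, dataset curation pipeline, evaluation protocol and retrosynthetic
route search used when training and assessing sequence models that predict
enzyme-catalysed reactions — without requiring any trained model. Pluggable
single-step predictors (deterministic lookup/template stubs ship with the
package; adapters for external seq2seq models plug into the same contract)
let every component run and be tested at desk scale.

## Who it is for

Cheminformaticians and ML practitioners building enzymatic reaction
prediction models: preparing training corpora from merged database exports,
evaluating forward/backward models under a product-disjoint protocol, and
searching multi-step biocatalytic routes to commercially available
precursors.

## What it implements

**Enzymatic reaction SMILES.** An ordinary reaction SMILES extended with an
Enzyme Commission number on the reactant side, `A|1.1.1>>B`. Both the ASCII
pipe and the typographic divides character (U+2223) are accepted on input;
ASCII is always emitted. All molecules are held in one fixed canonical form
(RDKit canonical isomeric SMILES), with stereochemistry preserved verbatim.

**EC token schemes (EC0–EC4).** For sequence models the EC number is
tokenised as one bracketed token per hierarchy level with the letter
prefixes `v`, `u`, `t`, `s` (levels 1–4), e.g.
`5.4.99 → [v5] [u5.4] [t5.4.99]`. Digits alone would collide with SMILES
ring closures; the cumulative path keeps tokens unique per branch of the EC
hierarchy. Scheme ECk truncates annotations to the first k levels (EC0 drops
them entirely).

**Curation.** Raw multi-source reaction tables are cleaned by four rules,
in order: (1) drop products that also appear as reactants; (2) in
multi-product records, strip known co-enzymes and common byproducts
(NAD(P)(H), ATP/ADP/AMP, coenzyme A, phosphate, diphosphate, water, CO₂, O₂,
H⁺ by default — fully overridable); (3) drop products with fewer than 4
heavy atoms; (4) keep only records with exactly one product and at least one
reactant. Survivors are truncated to the target scheme and deduplicated on
the canonical extended reaction SMILES, merging provenance. Truncation can
only merge records, so unique counts are monotone in scheme depth.

**Product-disjoint splits.** Records are grouped by product and whole
groups assigned to train/validation/test (default 90/5/5), so no product
ever appears in two splits — the protocol that prevents models from scoring
by memorising products. A 9:1 multitask weighting utility prepares combined
general-chemistry + enzymatic corpora for transfer learning, and a
training-config descriptor records the published transformer
hyper-parameters for external trainers (this toolkit never trains).

**Evaluation.** Top-k accuracy (exact canonical match; backward requires
the precursor set and the EC), backward EC-only accuracy, round-trip
accuracy (a backward proposal counts when the forward model's rank-1
product regenerates the target), per-class breakdowns, the 7×7 enzyme-class
confusion matrix, and EC-randomisation experiments (within/across class)
that probe whether a model actually uses the enzyme token.

**Route planning.** Level-synchronous beam search over partial routes: the
backward model proposes disconnections, each proposal is round-trip
filtered by the forward model, and surviving steps are scored

```
combined = p_fwd · exp(−λ · (mean(SC) − 1))
```

with SC a synthetic-complexity score on the SCScore-style 1–5 scale (a
closed-form heuristic by default, pluggable for a trained scorer) and
λ = 0.25 by default. A route's score is the product of its step scores;
branches terminate on commercial availability (a stock file) or at the
depth limit.

## Worked example

```python
from bioretro import (
    curate, plan, PlannerConfig, LookupForwardPredictor,
    TemplateBackwardPredictor, tokenize_enzymatic,
)
from bioretro.fixtures import FixtureSpec, make_raw_records, make_route_scenario

# a synthetic multi-source corpus with duplicates, cofactors and noise
records, manifest = make_raw_records(FixtureSpec(seed=7, n_reactions=100))
for scheme in ("EC0", "EC1", "EC2", "EC3", "EC4"):
    print(scheme, len(curate(records, scheme=scheme)))

print(" ".join(tokenize_enzymatic("CC(C)CO|1.1.1>>CC(C)C=O", "EC3").tokens))

# route search on a planted three-step scenario with decoy branches
target, rules, table, stock, scen = make_route_scenario(depth=3, branching=3, seed=7)
routes = plan(target, TemplateBackwardPredictor(rules),
              LookupForwardPredictor(table), stock,
              PlannerConfig(beam_width=10, max_depth=6))
best = routes[0]
print(f"best route: depth {best.depth}, score {best.route_score:.4f}")
```

prints

```
EC0 57
EC1 57
EC2 57
EC3 57
EC4 93
C C ( C ) C O [v1] [u1.1] [t1.1.1] > > C C ( C ) C = O
best route: depth 3, score 0.8869
```

The 112 raw records (100 reactions, 12 cross-source duplicates) collapse to
57 unique records at schemes EC0–EC3 and 93 at EC4: distinct level-4
serials keep records apart that merge once truncated. The tokenised
reaction shows the three cumulative-path EC tokens between the substrate
and the arrow. The planner recovers the planted three-step route (score
0.8869 = the product of the three step scores) while the decoy branches,
which never reach the stock, are discarded.

The same flows are available from the shell:

```bash
bioretro fixtures --seed 7 --n 100 --out-dir fx
bioretro curate --input fx/raw.tsv --scheme EC3 --output curated.tsv
bioretro split --input curated.tsv --scheme EC3 --seed 1 --out-dir splits
bioretro plan --target CCCO --stock fx/stock.txt \
    --rules fx/backward_rules.tsv --table fx/forward_table.tsv --out route.json
```

## Layout

| module | contents |
| --- | --- |
| `bioretro.chem_core` | canonicalisation, EC numbers, reaction SMILES grammar |
| `bioretro.tokenizer` | atom-level + EC tokenisation, seq2seq file export |
| `bioretro.curation` | filter rules, dedup, splits, multitask corpus, training config |
| `bioretro.predict` | predictor contract, lookup/template stubs, EC randomisation |
| `bioretro.evaluation` | top-k / EC-only / round-trip metrics, breakdowns, confusion |
| `bioretro.retro_planner` | complexity scoring, step scoring, beam search, route JSON |
| `bioretro.fixtures` | deterministic synthetic corpora and planted-route scenarios |
| `bioretro.cli` | `bioretro` command with the subcommands shown above |

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
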