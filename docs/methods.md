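# Methods

This note documents the models and procedures implemented by `bioretro`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical/design decisions taken where the
underlying conventions are genuinely open.

## Reaction representation

Reactions are SMILES-encoded with an optional Enzyme Commission (EC)
annotation on the reactant side: `A|1.1.1>>B`. The EC number is a 1–4 level
hierarchical identifier whose first level (1–7) is the enzyme class
(oxidoreductases, transferases, hydrolases, lyases, isomerases, ligases,
translocases). Levels are contiguous from level 1; truncation drops trailing
levels and never pads.

Every molecule is normalised to RDKit's canonical isomeric SMILES before any
comparison. Uniqueness, deduplication, stock membership and evaluation
matching are all exact string equality on that form, which makes the
pipeline's "unique reaction–EC combination" notion well defined.
Stereochemistry is preserved verbatim throughout; the evaluation layer
offers an explicit `ignore_stereo` switch that recomputes a metric on
stereo-stripped strings, because stereochemical assignment is the dominant
failure mode for isomerase-rich test sets and silently dropping isomeric
information anywhere else would corrupt exactly that analysis.

Three-part reaction SMILES (`r>agents>p`) are parsed and reserialised
faithfully; the enzymatic two-part form has no agents field, so
`fold_reagents` moves agents onto the reactant side before tokenisation or
curation. Both the ASCII `|` and the typographic `∣` (U+2223) are accepted
as EC delimiters on input; ASCII is always emitted, so files are stable.

## Tokenisation

Molecular text is split with the standard atom-level reaction-SMILES regex
(bracket atoms atomic, `Cl`/`Br` whole, `%nn` ring closures whole). EC
numbers become one bracketed token per level with letter prefixes `v`, `u`,
`t` for levels 1–3 — digits alone would collide with ring-closure digits —
and each token carries the cumulative path (`[u5.4]`, not `[u4]`): a
per-level-digit token would alias children of different parents and hide
the hierarchy from a sequence model. Two open choices were fixed here:

* **Level-4 prefix.** Only levels 1–3 have conventional prefixes; the EC4
  scheme needs a fourth, and we adopt `s` (configurable in principle; the
  constant is a one-line change).
* **Arrow policy.** `>>` is emitted as two `>` tokens. Seq2seq training
  files split source from target at the arrow, so the arrow never appears
  inside one side; the file writer, not the tokeniser, owns that split.

Detokenisation strips token-file spaces, validates the EC run (contiguous,
prefix order, each path extending the previous) and is the exact inverse of
tokenisation on ASCII-normalised text.

## Curation pipeline

Four rules, applied in this order per record:

1. remove products that also occur as reactants in the same reaction;
2. if the record has **more than one product at entry to this rule**,
   remove products found in the cofactor configuration (the gate is
   evaluated before the rule's own removals — a record reduced to one
   product by this rule is not re-entered);
3. remove products with heavy-atom count < 4 (a 4-heavy-atom product is
   kept);
4. keep only records with exactly one product and ≥ 1 reactant.

The shipped cofactor list holds the ubiquitous co-enzymes and byproducts
(NAD⁺/NADH, NADP⁺/NADPH, ATP/ADP/AMP, coenzyme A, phosphate, diphosphate,
water, CO₂, O₂, H⁺) and is fully overridable from a file of SMILES; curated
collections typically carry much longer institution-specific lists, and
nothing in the pipeline depends on this one's exact contents.

Surviving records have their EC truncated to the target scheme and are
deduplicated on (lexicographically sorted canonical reactants, truncated
EC, canonical product) — reactant order is explicitly not significant.
Provenance source tags are merged into a multiset on collision. Records
whose EC is shallower than the scheme keep the levels they have (levels are
never invented); deduplication happens **after** truncation, which is what
makes the unique-record counts monotone non-decreasing in scheme depth
(EC0 ≤ EC1 ≤ … ≤ EC4): truncation can only merge records, never split
them. Curation is idempotent: re-curating a curated dataset is the
identity.

## Product-disjoint splitting

Records are grouped by canonical product; whole groups are assigned to
splits so no product molecule appears in more than one of
train/validation/test (pairwise disjointness — the strongest reading, and
the one that actually prevents evaluation-by-memorisation in both
directions). Assignment is greedy: groups sorted largest-first (ties
shuffled by the seed) go to the split with the largest remaining deficit
against its target record count. This is deterministic given (dataset,
seed) and bounds every split's deviation from its target by the size of a
single product group. Default fractions are 0.90/0.05/0.05.

## Multitask corpus and training descriptor

Transfer learning from a large general-chemistry corpus to the small
enzymatic corpus uses weighted sampling; the default weights are 9:1
(general:enzymatic). `prepare_multitask_corpus` writes a manifest for
weighted-corpus trainers and can materialise an interleaved sample in which
each line is drawn independently with probability proportional to the
corpus weight — so the majority-corpus fraction of a large sample
concentrates at w/(Σw) with binomial fluctuation.

`emit_training_config` writes the published transformer hyper-parameters
(6 layers, model/embedding size 512, gradient accumulation 8, batch 4096
tokens, Adam β₁ 0.9 β₂ 0.998, learning rate 2.0 with noam decay, dropout
0.1, label smoothing 0.1, parameter initialisation disabled, position
encoding enabled) as a YAML descriptor for an external trainer. The toolkit
itself never trains a model.

## Predictors and evaluation

The single-step contract is `predict(query, k) → ranked candidates` with
ranks 1..k gap-free and confidences in [0, 1] non-increasing in rank
(`validate_predictions` enforces this for any adapter). Two deterministic
stubs make the metrics and the planner testable without a trained model:

* the **lookup forward stub** answers by exact (sorted substrates, EC)
  match in a curated table, ranking products by record multiplicity
  (provenance count) with confidence = normalised multiplicity;
* the **template backward stub** fires exact product-match disconnection
  rules ranked by declared priority, confidence = normalised priority.

Metrics: forward top-k matches the product string; backward top-k matches
the precursor **set** and, by default, the EC (a flag relaxes to
substrate-only matching, since conventions differ on whether the enzyme
token must be reproduced). EC-only accuracy ignores precursors and
therefore always dominates the full backward accuracy. **Round-trip
accuracy** is implemented as backward proposal → forward check: a target
counts when any of its top-k backward proposals, fed to the forward model,
regenerates the target at rank 1. (The opposite reading — forward first —
does not evaluate a retrosynthesis proposal's validity, so the
backward-first direction is the one implemented.) The class confusion
matrix tabulates true vs rank-1 predicted enzyme class with an explicit
`none` column so row sums always equal per-class counts.

**EC randomisation** probes whether a model uses the enzyme token: each
test record's EC is replaced by one drawn from the test set's own empirical
EC pool (not the universe of legal ECs), either within the record's level-1
class or across classes. The record's own EC is excluded from the
within-class pool when an alternative exists; a singleton class leaves the
record unchanged with a warning. Substrates and products are untouched, so
the (reactants, product) multiset is preserved exactly.

## Route planning

The planner is a level-synchronous beam search over partial route trees.
At each depth, every unsolved leaf of every beam candidate is expanded with
the backward model's top-k proposals; each proposal must pass the
**round-trip filter** (forward rank-1 regenerates the parent) — a hard
filter rather than a soft weight, mirroring the round-trip validity notion
used in evaluation and keeping all scores in [0, 1]. Surviving steps are
scored

    combined = p_fwd · exp(−λ · (mean(complexity) − 1)),    λ = 0.25

The exponential-penalty form is this package's own closed-form choice for
"forward confidence reweighted by precursor complexity": it is smooth,
monotone in both arguments, equals the forward confidence at λ = 0 or at
the complexity floor, and keeps the score a probability-like quantity. The
default complexity scorer is a closed-form heuristic on the 1–5 scale,

    1 + 0.04·(heavy_atoms − 1) + 0.35·rings + 0.25·stereocentres, clamped to [1, 5],

monotone in size, ring count and stereocentre count, with a single heavy
atom scoring exactly 1. It is a pluggable default — any callable mapping a
SMILES to [1, 5], such as a trained synthetic-complexity model, can replace
it.

A route's score is the **product** of its step scores (an aggregation the
underlying search literature leaves open; the product reads as a joint
success confidence and makes route scores comparable across depths in the
same way step scores are). The beam keeps the top `beam_width` partial
routes per level; a branch closes as solved when every leaf is in the stock
and is abandoned at `max_depth`. A molecule may not reappear on its own
ancestor path (cycle guard). Ties are broken lexicographically on
serialised precursors, so the search is deterministic for deterministic
models — the config's `seed` field is reserved for stochastic adapters. A
target already in stock returns the trivial zero-step route. With a beam at
least as wide as the total branching the solved set provably equals
exhaustive enumeration, which the tests check against an independent
recursive enumerator on small instances.

Solved routes serialise to nested JSON (molecule, EC, per-step confidences
and complexities, children) with a lossless parser. The `plan` CLI also
offers an interactive mode printing expansions per level and accepting a
branch index.

## Synthetic data generator

The generator emulates the *conditions* of merged public reaction
collections, not their chemistry: multi-source records with cross-source
duplicates (rate 0.10), cofactor products injected into otherwise
single-product records (rate 0.15), tiny byproducts below the heavy-atom
threshold (rate 0.10), and EC numbers at all four levels across all seven
classes (uniform class mix by default). Reactions come from a closed
template grammar — oxidation, transamination, ester hydrolysis,
dehydration, isomerisation, amide ligation and phosphoryl transfer over a
~20-block alcohol/acid/amine alphabet — chosen so every product clears the
4-heavy-atom threshold and brute-force oracles run in well under a second.
Template families carry fixed EC level-3 paths consistent with their
chemistry class purely as labels. The injection rates are modelling
choices for a realistic level of noise pollution in merged database
exports; they are not fit to any dataset.

The generator emits a manifest with the expected post-curation survivor
set per scheme, computed from each record's clean (pre-injection) form —
i.e. independently of the curation code — so tests compare the pipeline
against ground truth rather than against itself. `make_route_scenario`
builds planner instances with exactly one solvable planted route plus
decoy disconnections that pass the round-trip filter but lead to leaves
outside the stock.

**What passing tests do and do not show.** The generator's molecules are
small aliphatics; real metabolic datasets are dominated by large,
stereochemistry-rich natural products, have heavily imbalanced class
distributions, and contain genuinely ambiguous records (identical
substrate + EC with different products). Green tests therefore certify the
*mechanics* — grammar, rules, splits, metrics, search — under controlled
conditions, not predictive performance on real enzymatic chemistry, which
is entirely a property of the plugged-in models and data.

## Degenerate inputs and numerical notes

* Unparseable raw rows are logged and counted, never silently dropped.
* Splitting requires ≥ 3 distinct products; fewer is an error.
* `topk_accuracy` on an empty record list is an error (not 0/0 = 0).
* Model exceptions during round-trip evaluation or expansion count the
  affected record incorrect / produce an empty expansion, with a log line.
* Confidence monotonicity checks allow 1e-12 slack for float noise.
* Per-route child combinations are capped (default 1000 per partial per
  level) to bound worst-case cartesian growth on adversarial stubs; the
  cap is far above anything the shipped scenarios produce.

## Known limitations

* The default complexity heuristic captures size/ring/stereocentre trends
  only; it is not a substitute for a learned synthetic-accessibility model
  when ranking chemically diverse precursors.
* The template backward stub matches products exactly; it does not perform
  substructure rewrites, which is sufficient for testing the contract but
  not for real single-step retrosynthesis.
* Beam search over whole partial routes enumerates combinations of leaf
  expansions; very wide AND-branching with a wide beam can be expensive
  (bounded by the combination cap).
* Dataset sizes of real curated collections depend on source-database
  versions and the canonicalisation flavour; this package fixes the
  canonicalisation but makes no attempt to reproduce any particular
  published record count.
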