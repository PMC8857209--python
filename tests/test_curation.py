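"""The four filter rules, deduplication, splits and corpus preparation."""

import pytest

from bioretro import (
    CofactorConfig,
    CuratedDataset,
    MultitaskWeights,
    RawRecord,
    SplitSpec,
    canonicalize,
    curate,
    emit_training_config,
    parse_reaction_smiles,
    prepare_multitask_corpus,
    product_disjoint_split,
)
from bioretro.curation import (
    read_raw_tsv,
    read_training_config,
    rule1_remove_self_products,
    rule2_strip_cofactors,
    rule3_remove_small_products,
    rule4_validity_filter,
)
from bioretro.fixtures import FixtureSpec, make_raw_records

from conftest import EXPECTED_SURVIVORS_EC3

PHOSPHATE = canonicalize("OP(=O)(O)O")


def rxn(text):
    return parse_reaction_smiles(text)


class TestRules:
    def test_rule1_removes_products_present_as_reactants(self):
        out = rule1_remove_self_products(rxn("CCO.O>>CC=O.O"))
        assert out.products == (canonicalize("CC=O"),)
        assert len(out.reactants) == 2  # reactant side untouched

    def test_rule1_fully_self_product(self):
        assert rule1_remove_self_products(rxn("CCO>>CCO")).products == ()

    def test_rule1_no_overlap_is_identity(self):
        r = rxn("CCO>>CC=O")
        assert rule1_remove_self_products(r) == r

    def test_rule2_strips_cofactor_from_multi_product(self):
        cfg = CofactorConfig(coenzymes=frozenset({PHOSPHATE}), byproducts=frozenset())
        out = rule2_strip_cofactors(rxn("CCCCO>>CCCC=O.OP(=O)(O)O"), cfg)
        assert out.products == (canonicalize("CCCC=O"),)

    def test_rule2_single_product_untouched_even_when_listed(self):
        cfg = CofactorConfig(coenzymes=frozenset({PHOSPHATE}), byproducts=frozenset())
        r = rxn("CCCCO>>OP(=O)(O)O")
        assert rule2_strip_cofactors(r, cfg) == r

    def test_rule2_unlisted_products_unchanged(self):
        cfg = CofactorConfig.default()
        r = rxn("CCCCO>>CCCC=O.NCCCC")
        assert rule2_strip_cofactors(r, cfg) == r

    @pytest.mark.parametrize(
        "text,kept",
        [
            ("C>>CC(=O)OCC.O", ("CCOC(C)=O",)),  # water (1 atom) removed
            ("C>>CC(=O)O", ("CC(=O)O",)),  # exactly 4 heavy atoms retained
            ("C>>CCO", ()),  # 3 heavy atoms removed
        ],
    )
    def test_rule3_heavy_atom_boundary(self, text, kept):
        assert rule3_remove_small_products(rxn(text)).products == tuple(
            canonicalize(k) for k in kept
        )

    @pytest.mark.parametrize(
        "text,keep",
        [
            ("CC(=O)O.CCO>>CCOC(C)=O", True),
            ("CCCCO>>CCCC=O.NCCCC", False),  # two products
            (">>CCCC=O", False),  # no reactants
            ("CCCCO>>", False),  # no products
        ],
    )
    def test_rule4_validity(self, text, keep):
        assert rule4_validity_filter(rxn(text)) is keep


class TestCurate:
    def test_hand_audited_fixture_yields_expected_survivors(self, twelve_records):
        ds = curate(twelve_records, scheme="EC3")
        assert sorted(ds.extended_smiles()) == EXPECTED_SURVIVORS_EC3
        assert len(ds) == 7

    def test_provenance_merged_on_dedup(self, twelve_records):
        ds = curate(twelve_records, scheme="EC3")
        by_smiles = dict(zip(ds.extended_smiles(), ds.provenance))
        oxidation = [k for k in by_smiles if k.startswith("CCCO|")][0]
        assert sorted(by_smiles[oxidation]) == ["brenda", "rhea"]

    def test_curate_is_idempotent(self, twelve_records):
        once = curate(twelve_records, scheme="EC3")
        again = curate(
            [RawRecord(rxn=r, source=p[0]) for r, p in zip(once.records, once.provenance)],
            scheme="EC3",
        )
        assert sorted(again.extended_smiles()) == sorted(once.extended_smiles())

    def test_ec4_keeps_truncation_pair_apart(self, twelve_records):
        assert len(curate(twelve_records, scheme="EC4")) == 8

    def test_same_reaction_different_serial_merges_at_ec3(self):
        records = [
            RawRecord(rxn=rxn("CCCCO|1.1.1.1>>CCCC=O"), source="a"),
            RawRecord(rxn=rxn("CCCCO|1.1.1.2>>CCCC=O"), source="b"),
        ]
        assert len(curate(records, scheme="EC4")) == 2
        assert len(curate(records, scheme="EC3")) == 1

    def test_empty_input(self):
        assert len(curate([], scheme="EC3")) == 0

    def test_scheme_monotonicity_on_random_corpora(self):
        for seed in range(10):
            records, _ = make_raw_records(FixtureSpec(seed=seed, n_reactions=40))
            counts = [len(curate(records, scheme=s)) for s in
                      ("EC0", "EC1", "EC2", "EC3", "EC4")]
            assert counts == sorted(counts)

    def test_every_record_single_product_with_four_heavy_atoms(self, twelve_records):
        from bioretro import heavy_atom_count

        ds = curate(twelve_records, scheme="EC3")
        for r in ds.records:
            assert len(r.products) == 1
            assert heavy_atom_count(r.products[0]) >= 4
            assert len(r.reactants) >= 1

    def test_tsv_round_trip(self, twelve_records, tmp_path):
        ds = curate(twelve_records, scheme="EC3")
        path = tmp_path / "ds.tsv"
        ds.write_tsv(path)
        loaded = CuratedDataset.read_tsv(path, scheme="EC3")
        assert sorted(loaded.extended_smiles()) == sorted(ds.extended_smiles())

    def test_read_raw_tsv_skips_and_counts_bad_rows(self, tmp_path):
        path = tmp_path / "raw.tsv"
        path.write_text(
            "rxn_smiles\tec\tsource\n"
            "CCCO|1.1.1.1>>CCC=O\t\trhea\n"
            "not-a-reaction\t\trhea\n"
            "CCO|9.1.1>>CC=O\t\tbrenda\n",
            encoding="utf-8",
        )
        records, skipped = read_raw_tsv(path)
        assert len(records) == 1
        assert skipped == 2


@pytest.fixture(scope="module")
def dataset():
    records, _ = make_raw_records(FixtureSpec(seed=11, n_reactions=120))
    return curate(records, scheme="EC3")


class TestSplit:

    def test_zero_product_overlap(self, dataset):
        for seed in range(10):
            train, valid, test = product_disjoint_split(dataset, SplitSpec(seed=seed))
            assert not train.products() & valid.products()
            assert not train.products() & test.products()
            assert not valid.products() & test.products()
            assert len(train) + len(valid) + len(test) == len(dataset)

    def test_shared_product_group_stays_together(self):
        texts = [f"{'C' * (i + 4)}O|1.1.1.{i + 1}>>CCCC=O" for i in range(10)]
        texts += ["CCCCCCCCCO|2.6.1.1>>NCCCC", "CCCCCCCCCCO|3.1.1.1>>CCCC(=O)O"]
        ds = curate(
            [RawRecord(rxn=rxn(t), source="x") for t in texts], scheme="EC4"
        )
        shared = canonicalize("CCCC=O")
        train, valid, test = product_disjoint_split(ds, SplitSpec(seed=0))
        homes = [
            part for part in (train, valid, test) if shared in part.products()
        ]
        assert len(homes) == 1
        assert sum(1 for r in homes[0].records if r.products[0] == shared) == 10

    def test_deterministic_given_seed(self, dataset):
        a = product_disjoint_split(dataset, SplitSpec(seed=5))
        b = product_disjoint_split(dataset, SplitSpec(seed=5))
        for x, y in zip(a, b):
            assert x.extended_smiles() == y.extended_smiles()

    def test_fraction_deviation_bounded_by_largest_group(self, dataset):
        groups = {}
        for r in dataset.records:
            groups[r.products[0]] = groups.get(r.products[0], 0) + 1
        bound = max(groups.values())
        for seed in range(5):
            parts = product_disjoint_split(dataset, SplitSpec(seed=seed))
            for part, frac in zip(parts, (0.90, 0.05, 0.05)):
                assert abs(len(part) - frac * len(dataset)) <= bound

    def test_too_few_products_rejected(self):
        ds = curate(
            [RawRecord(rxn=rxn("CCCO|1.1.1.1>>CCC=O"), source="x")], scheme="EC3"
        )
        with pytest.raises(ValueError):
            product_disjoint_split(ds, SplitSpec())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.2))
        with pytest.raises(ValueError):
            SplitSpec(fractions=(1.0, 0.0, 0.0))


class TestMultitaskCorpus:
    def _write_corpus(self, tmp_path, name, lines):
        src = tmp_path / f"{name}.src"
        tgt = tmp_path / f"{name}.tgt"
        src.write_text("".join(f"{name} S {i}\n" for i in range(lines)))
        tgt.write_text("".join(f"{name} T {i}\n" for i in range(lines)))
        return str(src), str(tgt)

    def test_manifest_and_sample(self, tmp_path):
        corpora = {
            "uspto": self._write_corpus(tmp_path, "uspto", 50),
            "ecreact": self._write_corpus(tmp_path, "ecreact", 20),
        }
        manifest = prepare_multitask_corpus(
            corpora,
            MultitaskWeights({"uspto": 9, "ecreact": 1}),
            tmp_path / "out",
            sample_lines=2000,
            seed=1,
        )
        assert manifest["corpora"]["uspto"]["weight"] == 9
        counts = manifest["sample"]["counts"]
        assert counts["uspto"] + counts["ecreact"] == 2000
        # 99% binomial CI around 0.9 with n=2000: half-width ~0.0173
        assert abs(counts["uspto"] / 2000 - 0.9) <= 2.576 * (0.9 * 0.1 / 2000) ** 0.5

    def test_single_corpus_weight_one(self, tmp_path):
        corpora = {"only": self._write_corpus(tmp_path, "only", 5)}
        manifest = prepare_multitask_corpus(
            corpora, MultitaskWeights({"only": 1}), tmp_path / "out"
        )
        assert manifest["corpora"]["only"]["weight"] == 1
        assert manifest["sample"] is None

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            MultitaskWeights({"a": 0})

    def test_mismatched_line_counts_rejected(self, tmp_path):
        src, _ = self._write_corpus(tmp_path, "a", 5)
        _, tgt = self._write_corpus(tmp_path, "b", 7)
        with pytest.raises(ValueError):
            prepare_multitask_corpus(
                {"a": (src, tgt)}, MultitaskWeights({"a": 1}), tmp_path / "out"
            )


class TestTrainingConfig:
    def test_descriptor_round_trips(self, tmp_path):
        path = tmp_path / "train.yaml"
        config = emit_training_config(path)
        assert config["layers"] == 6
        assert config["word_vec_size"] == 512
        assert config["adam_beta2"] == 0.998
        assert read_training_config(path) == config

    def test_override_reflected(self, tmp_path):
        path = tmp_path / "train.yaml"
        emit_training_config(path, dropout=0.3)
        assert read_training_config(path)["dropout"] == 0.3
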