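"""Filtering, split assignment, EC encoding, and corpus I/O."""

from collections import Counter

import pytest

import retrotag as rt
from retrotag.dataset import FilterConfig, ec_tokens

from conftest import ESTERIFICATION

LACTONIZATION = "[OH:1][CH2:2][CH2:3][CH2:4][C:5](=[O:6])[OH:7]>>[O:1]1[CH2:2][CH2:3][CH2:4][C:5]1=[O:6]"


class TestFilterReaction:
    def test_esterification_kept(self, esterification):
        site = rt.find_changed_atoms(esterification)
        assert rt.filter_reaction(esterification, site) == (True, None)

    def test_single_reactant_dropped(self):
        rxn = rt.parse_reaction_line(LACTONIZATION)
        site = rt.find_changed_atoms(rxn)
        assert rt.filter_reaction(rxn, site) == (False, "reactant_count")

    def test_oversized_site_dropped(self, esterification):
        big = rt.DisconnectionSite(frozenset(range(1, 12)))
        assert rt.filter_reaction(esterification, big) == (False, "too_many_tags")

    def test_empty_site_dropped(self, esterification):
        empty = rt.DisconnectionSite(frozenset())
        assert rt.filter_reaction(esterification, empty) == (False, "no_tags")

    def test_token_limit(self, esterification):
        site = rt.find_changed_atoms(esterification)
        cfg = FilterConfig(max_tokens=3)
        assert rt.filter_reaction(esterification, site, cfg) == (False, "token_limit")

    def test_invalid_config_rejected(self):
        with pytest.raises(rt.DatasetError):
            FilterConfig(min_reactants=5, max_reactants=2)


class TestBuildVariantCorpus:
    def test_disconnection_aware_example(self, esterification):
        records, drops = rt.build_variant_corpus([esterification], "disconnection_aware")
        assert not drops
        (record,) = records
        assert record.src == rt.canonicalize("C[C:1](=O)[O:1]CC", keep_maps=True)
        assert record.tgt == "CC(=O)O.CCO"
        assert record.n_tags == 2

    def test_autotag_example(self, esterification):
        (record,), _ = rt.build_variant_corpus([esterification], "autotag")
        assert record.src == "CCOC(C)=O"
        assert record.tgt == rt.canonicalize("C[C:1](=O)[O:1]CC", keep_maps=True)

    def test_permuted_single_tag_contributes_nothing(self):
        # a one-atom edit: tert-alcohol dehydration to isobutylene analogue
        line = "[CH3:1][C:2]([CH3:3])([CH3:4])[OH:5].[CH4:6]>>[CH3:1][C:2]([CH3:3])([CH3:4])[CH3:6]"
        cfg = FilterConfig(min_reactants=1)
        rxn = rt.parse_reaction_line(line)
        assert rt.find_changed_atoms(rxn).n_tags == 2  # C2 and C6 both edited
        one_tag = "[CH3:1][C:2]([CH3:3])([CH3:4])[OH:5]>>[CH3:1][CH:2]([CH3:3])[CH3:4]"
        records, drops = rt.build_variant_corpus([one_tag], "permuted", cfg)
        assert records == []
        assert not drops  # passed the filter; simply no permutations exist

    def test_permuted_and_autocomplete_reproducible(self, fixture_set):
        lines = [f.line for f in fixture_set[:40]]
        for variant in ("permuted", "autocomplete"):
            r1, _ = rt.build_variant_corpus(lines, variant, seed=9)
            r2, _ = rt.build_variant_corpus(lines, variant, seed=9)
            assert r1 == r2

    def test_drop_reasons_logged(self, fixture_set):
        lines = [f.line for f in fixture_set[:20]]
        lines.append(LACTONIZATION)                     # reactant_count
        lines.append("[CH3:1][OH:2].[CH4:3]>>[CH3:1][OH:2]")  # no_tags
        _, drops = rt.build_variant_corpus(lines, "disconnection_aware")
        assert drops == Counter({"reactant_count": 1, "no_tags": 1})

    def test_unknown_variant_rejected(self):
        with pytest.raises(rt.DatasetError):
            rt.build_variant_corpus([], "beam_search")


class TestAssignSplits:
    def test_exact_90_5_5_without_leakage(self):
        fx = rt.generate_dataset(1000, seed=42)
        records, drops = rt.build_variant_corpus([f.line for f in fx], "disconnection_aware")
        assert len(records) == 1000 and not drops
        split = rt.assign_splits(records, seed=0)
        counts = Counter(r.split for r in split)
        assert counts == Counter({"train": 900, "valid": 50, "test": 50})
        by_product = {}
        for r in split:
            by_product.setdefault(r.product, set()).add(r.split)
        assert all(len(s) == 1 for s in by_product.values())

    def test_deterministic_under_seed(self, fixture_set):
        records, _ = rt.build_variant_corpus([f.line for f in fixture_set], "disconnection_aware")
        a = rt.assign_splits(records, seed=3)
        b = rt.assign_splits(records, seed=3)
        assert a == b

    def test_grouping_keeps_products_together(self, fixture_set):
        # two records per product via two variants sharing the product key
        lines = [f.line for f in fixture_set[:40]]
        da, _ = rt.build_variant_corpus(lines, "disconnection_aware")
        at, _ = rt.build_variant_corpus(lines, "autotag")
        split = rt.assign_splits(da + at, seed=1)
        by_product = {}
        for r in split:
            by_product.setdefault(r.product, set()).add(r.split)
        assert all(len(s) == 1 for s in by_product.values())

    def test_too_few_records_rejected(self, esterification):
        records, _ = rt.build_variant_corpus([esterification], "disconnection_aware")
        with pytest.raises(rt.DatasetError):
            rt.assign_splits(records)

    def test_bad_ratios_rejected(self, fixture_set):
        records, _ = rt.build_variant_corpus([f.line for f in fixture_set[:10]], "autotag")
        with pytest.raises(rt.DatasetError):
            rt.assign_splits(records, ratios=(80, 10, 5))


class TestECHandling:
    def test_encoding_example(self):
        assert ec_tokens("1.1.1.1") == ("[EC1_1]", "[EC2_1]", "[EC3_1]", "[EC4_1]")
        record = rt.PromptRecord(
            src_tokens=("C", "C", "=", "O"), tgt_tokens=("C",),
            variant="autotag", n_tags=1, product="CC=O",
        )
        attached = rt.attach_ec(record, "1.1.1.1")
        assert attached.src_tokens == ("C", "C", "=", "O", "|", "[EC1_1]", "[EC2_1]", "[EC3_1]", "[EC4_1]")

    def test_strip_attach_identity(self, enzymatic_set):
        records, _ = rt.build_variant_corpus(
            [f.line for f in enzymatic_set], "disconnection_aware"
        )
        assert records
        for record in records:
            assert record.ec_number is not None
            stripped = rt.strip_ec(record)
            assert rt.attach_ec(stripped, record.ec_number) == record
            assert rt.strip_ec(stripped) == stripped

    def test_malformed_ec_rejected(self):
        with pytest.raises(rt.DatasetError):
            ec_tokens("1.2.3")

    def test_tagging_ignores_ec_suffix(self, enzymatic_set):
        for fx in enzymatic_set[:10]:
            with_ec = rt.parse_reaction_line(fx.line)
            without = rt.parse_reaction_line(fx.line.split(" |EC:")[0])
            assert rt.find_changed_atoms(with_ec) == rt.find_changed_atoms(without)


class TestCorpusIO:
    def test_write_read_roundtrip(self, fixture_set, tmp_path):
        records, _ = rt.build_variant_corpus([f.line for f in fixture_set], "disconnection_aware")
        records = rt.assign_splits(records, seed=2)
        rt.write_corpus(records, tmp_path)
        back = rt.read_corpus(tmp_path)
        assert sorted(back, key=lambda r: (r.split, r.src)) == sorted(
            records, key=lambda r: (r.split, r.src)
        )

    def test_split_line_counts(self, tmp_path):
        fx = rt.generate_dataset(1000, seed=42)
        records, _ = rt.build_variant_corpus([f.line for f in fx], "disconnection_aware")
        rt.write_corpus(rt.assign_splits(records, seed=0), tmp_path)
        train = (tmp_path / "src-train.txt").read_text().splitlines()
        assert len(train) == 900

    def test_mismatched_line_counts_rejected(self, fixture_set, tmp_path):
        records, _ = rt.build_variant_corpus([f.line for f in fixture_set[:10]], "autotag")
        rt.write_corpus(rt.assign_splits(records, seed=0), tmp_path)
        src_train = tmp_path / "src-train.txt"
        lines = src_train.read_text().splitlines()
        src_train.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(rt.DatasetError, match="integrity"):
            rt.read_corpus(tmp_path)

    def test_every_line_detokenizes_to_parseable_smiles(self, fixture_set, tmp_path):
        lines = [f.line for f in fixture_set[:40]]
        for variant in rt.dataset.VARIANTS:
            records, _ = rt.build_variant_corpus(lines, variant, seed=4)
            for r in records:
                rt.canonicalize(r.src.split("|")[0].strip() or r.src)
                for component in r.tgt.split("."):
                    rt.canonicalize(component)
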