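"""Disconnection-site detection and tag-grammar round-trips."""

import random

import pytest

import retrotag as rt
from retrotag.tagging import site_on_product

from conftest import DIELS_ALDER, ESTERIFICATION


class TestFindChangedAtoms:
    def test_esterification_site(self, esterification):
        site = rt.find_changed_atoms(esterification)
        assert site.atom_map_ids == frozenset({2, 7})
        assert site.n_tags == 2

    def test_diels_alder_every_atom_changes(self):
        rxn = rt.parse_reaction_line(DIELS_ALDER)
        site = rt.find_changed_atoms(rxn)
        assert site.atom_map_ids == frozenset({1, 2, 3, 4, 5, 6})

    def test_identical_sides_give_empty_site(self):
        rxn = rt.parse_reaction_line("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        site = rt.find_changed_atoms(rxn)
        assert site.n_tags == 0
        assert not site

    def test_unmapped_product_atom_rejected(self):
        rxn = rt.parse_reaction_line("[CH3:1][OH:2]>>[CH3:1]OC")
        with pytest.raises(rt.MappingError):
            rt.find_changed_atoms(rxn)

    def test_map_relabeling_permutes_site_identically(self, esterification):
        # relabel 1..7 -> 11..17: the site must follow the permutation
        line = ESTERIFICATION
        for old in range(7, 0, -1):
            line = line.replace(f":{old}]", f":{old + 10}]")
        relabeled = rt.parse_reaction_line(line)
        site = rt.find_changed_atoms(relabeled)
        assert site.atom_map_ids == frozenset({12, 17})

    def test_matches_generator_annotation(self, fixture_set):
        for fx in fixture_set:
            rxn = rt.parse_reaction_line(fx.line)
            assert rt.find_changed_atoms(rxn).atom_map_ids == fx.site.atom_map_ids

    def test_hydrogen_only_changes_opt_in(self):
        # deprotonation-style H change with identical heavy-atom bonds
        rxn = rt.parse_reaction_line("[CH3:1][NH2:2].[CH3:3][OH:4]>>[CH3:1][NH:2][CH3:3]")
        site = rt.find_changed_atoms(rxn)
        assert 1 not in site.atom_map_ids  # heavy bonds of C1 unchanged
        with_h = rt.find_changed_atoms(rxn, include_h_changes=True)
        assert site.atom_map_ids <= with_h.atom_map_ids


class TestTagGrammar:
    def test_insert_tags_esterification(self, esterification):
        site = rt.find_changed_atoms(esterification)
        tagged = rt.insert_tags(esterification.product, site)
        assert tagged.smiles == rt.canonicalize("C[C:1](=O)[O:1]CC", keep_maps=True)
        assert tagged.n_tags == 2

    def test_empty_site_gives_bare_product(self, esterification):
        tagged = rt.insert_tags(esterification.product, rt.DisconnectionSite(frozenset()))
        assert tagged.smiles == "CCOC(C)=O"
        assert tagged.n_tags == 0

    def test_full_site_tags_every_atom(self, esterification):
        site = rt.DisconnectionSite(frozenset({1, 2, 3, 5, 6, 7}))  # all product atoms
        tagged = rt.insert_tags(esterification.product, site)
        assert tagged.n_tags == 6

    def test_absent_map_id_rejected(self, esterification):
        with pytest.raises(rt.TaggingError):
            rt.insert_tags(esterification.product, rt.DisconnectionSite(frozenset({99})))

    def test_strip_tags_untagged_input(self):
        bare, site = rt.strip_tags("CC(=O)OCC")
        assert bare == "CCOC(C)=O"
        assert site.n_tags == 0

    def test_strip_accepts_sequential_tag_numbers(self):
        bare1, site1 = rt.strip_tags("C[C:1](=O)[O:1]CC")
        bare2, site2 = rt.strip_tags("C[C:1](=O)[O:2]CC")
        assert (bare1, site1) == (bare2, site2)

    def test_roundtrip_over_fixtures(self, fixture_set):
        """insert_tags and strip_tags are mutually inverse on every fixture."""
        for fx in fixture_set:
            rxn = rt.parse_reaction_line(fx.line)
            tagged = rt.insert_tags(rxn.product, fx.site)
            bare, site = rt.strip_tags(tagged)
            assert bare == fx.product
            assert site == site_on_product(rxn.product, fx.site)


class TestRecomputeSite:
    def test_oracle_prediction_recovers_prompt(self, esterification, mapper):
        site = rt.find_changed_atoms(esterification)
        prompt = site_on_product(esterification.product, site)
        recomputed = rt.recompute_site(
            esterification.product.bare_smiles, ["CC(=O)O", "CCO"], mapper
        )
        assert recomputed == prompt

    def test_wrong_site_precursors_differ(self, multi_site_set, oracle, mapper):
        product = multi_site_set[0]
        a, b = product.sites[0], product.sites[1]
        wrong = oracle.translate(b.tagged).top1
        recomputed = rt.recompute_site(product.product, list(wrong), mapper)
        assert recomputed is not None
        assert recomputed != a.canonical_site
        assert recomputed == b.canonical_site

    def test_product_as_its_own_precursor_gives_empty_site(self, mapper):
        recomputed = rt.recompute_site("CCOC(C)=O", ["CCOC(C)=O"], mapper)
        assert recomputed is not None
        assert recomputed.atom_indices == frozenset()

    def test_mapper_failure_yields_none(self, mapper):
        # no registered template explains methane + ethane -> ester
        assert rt.recompute_site("CCOC(C)=O", ["C", "CC"], mapper) is None


def test_canonical_site_invariant_to_input_atom_order(fixture_set):
    from rdkit import Chem

    from retrotag.chem_io import mol_from_smiles

    rng = random.Random(1)
    for fx in fixture_set[:25]:
        rxn = rt.parse_reaction_line(fx.line)
        reference = site_on_product(rxn.product, fx.site)
        mol = mol_from_smiles(rxn.product.smiles)
        order = list(range(mol.GetNumAtoms()))
        rng.shuffle(order)
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        assert site_on_product(shuffled, fx.site) == reference
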