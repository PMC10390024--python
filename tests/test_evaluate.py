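"""Round-trip, disconnection, ground-truth, diversity, and stratification."""

import random

import pytest

import retrotag as rt
from retrotag.evaluate import BinStat, EvalRecord


def _eval_inputs(fixtures):
    out = []
    for fx in fixtures:
        rxn = rt.parse_reaction_line(fx.line)
        out.append(rt.EvalInput.from_reaction(rxn, fx.site))
    return out


def _oracle_results(fixtures, oracle):
    out = []
    for fx in fixtures:
        rxn = rt.parse_reaction_line(fx.line)
        out.append(oracle.translate(rt.insert_tags(rxn.product, fx.site)))
    return out


class TestRoundTrip:
    def test_oracle_prediction_regenerates_product(self, forward):
        ok, product = rt.round_trip_match("CCOC(C)=O", ["CC(=O)O", "CCO"], forward)
        assert ok and product is not None

    def test_product_as_prediction_fails_forward(self, forward):
        ok, product = rt.round_trip_match("CCOC(C)=O", ["CCOC(C)=O"], forward)
        assert not ok and product is None

    def test_spectator_in_prediction_is_harmless(self, forward):
        ok, _ = rt.round_trip_match("CCOC(C)=O", ["CC(=O)O", "CCO", "c1ccncc1"], forward)
        assert ok


class TestDisconnectionMatch:
    def test_oracle_exact_on_single_site(self, fixture_set, oracle, forward, mapper):
        fixtures = fixture_set[:40]
        records, report = rt.evaluate_all(
            _eval_inputs(fixtures), _oracle_results(fixtures, oracle), forward, mapper
        )
        assert report.overall_disconnection == 1.0
        assert report.overall_round_trip == 1.0
        assert report.n_valid == len(fixtures)

    def test_control_is_strictly_worse_at_rare_sites(
        self, multi_site_set, oracle, naive, forward, mapper
    ):
        """High round-trip with low disconnection accuracy: the two metrics
        are independent, as for a tag-blind baseline."""
        inputs, naive_results = [], []
        for product in multi_site_set:
            rare = product.sites[-1]
            gt = oracle.translate(rare.tagged).top1
            inputs.append(
                rt.EvalInput(
                    product=product.product,
                    prompt=rare.canonical_site,
                    gt_precursors=gt,
                    gt_mapped=gt,
                    n_tags=rare.canonical_site.n_tags,
                )
            )
            naive_results.append(naive.translate(rare.tagged, top_n=1))
        _, report = rt.evaluate_all(inputs, naive_results, forward, mapper)
        assert report.overall_disconnection < 1.0
        assert report.overall_round_trip > report.overall_disconnection

    def test_lenient_mode_accepts_supersets(self, mapper):
        prompt = rt.CanonicalSite(product="CCOC(C)=O", atom_indices=frozenset({4}))
        ok_strict, _ = rt.disconnection_site_match(
            prompt, ["CC(=O)O", "CCO"], "CCOC(C)=O", mapper
        )
        ok_lenient, _ = rt.disconnection_site_match(
            prompt, ["CC(=O)O", "CCO"], "CCOC(C)=O", mapper, lenient=True
        )
        assert not ok_strict and ok_lenient


class TestGtMatch:
    def test_extra_reagent_matches_only_without_unmapped(self, mapper):
        gt_all = ("CC(=O)O", "CCO", "c1ccncc1")
        gt_mapped = ("CC(=O)O", "CCO")
        prediction = ["CC(=O)O", "CCO"]
        assert not rt.gt_match(prediction, gt_all)
        assert rt.gt_match(
            prediction, gt_mapped, exclude_unmapped=True, mapper=mapper, product="CCOC(C)=O"
        )

    def test_missing_reactant_fails_both_modes(self, mapper):
        gt = ("CC(=O)O", "CCO")
        assert not rt.gt_match(["CCO"], gt)
        assert not rt.gt_match(
            ["CCO"], gt, exclude_unmapped=True, mapper=mapper, product="CCOC(C)=O"
        )

    def test_identical_sets_match_in_both_modes(self, mapper):
        gt = ("CC(=O)O", "CCO")
        assert rt.gt_match(["CCO", "OC(C)=O"], gt)
        assert rt.gt_match(
            ["CCO", "OC(C)=O"], gt, exclude_unmapped=True, mapper=mapper, product="CCOC(C)=O"
        )

    def test_topn(self, oracle, esterification):
        site = rt.find_changed_atoms(esterification)
        result = oracle.translate(rt.insert_tags(esterification.product, site))
        assert rt.topn_gt_match(result, ["CC(=O)O", "CCO"], n=10)
        assert not rt.topn_gt_match(result, ["CCBr"], n=10)


class TestClassDiversity:
    def test_unique_label_count(self):
        class Stub:
            labels = iter(["A", "A", "B", "C", "C", "C", "A", "B", "D", "D"])

            def classify(self, reaction_smiles):
                return next(self.labels)

        predictions = [("C",)] * 10
        assert rt.class_diversity(predictions, "CC", Stub()) == 4

    def test_unclassifiable_excluded(self, classifier):
        predictions = [("CC(=O)O", "CCO"), ("C", "CC")]
        assert rt.class_diversity(predictions, "CCOC(C)=O", classifier) == 1

    def test_single_prompt_yields_one_class(self, multi_site_set, oracle, classifier):
        for product in multi_site_set[:10]:
            result = oracle.translate(product.sites[0].tagged)
            assert rt.class_diversity(result.ranked, product.product, classifier) == 1

    def test_site_enumeration_multiplies_diversity(
        self, multi_site_set, oracle, classifier
    ):
        for product in multi_site_set[:10]:
            pooled = rt.pooled_translate([s.tagged for s in product.sites], oracle)
            diversity = rt.class_diversity(pooled.ranked, product.product, classifier)
            assert diversity == len(product.sites) >= 2


class TestStratify:
    def _record(self, n_in, n_pred, disc, rtp):
        return EvalRecord(
            n_tags_input=n_in,
            n_tags_predicted=n_pred,
            round_trip=rtp,
            disconnection_match=disc,
            gt_match_all=False,
            gt_match_mapped_only=False,
        )

    def test_bin_accuracy_arithmetic(self):
        records = [self._record(2, 2, i < 7, True) for i in range(10)]
        report = rt.stratify(records)
        assert report.disconnection_by_input_tags[2] == BinStat(count=10, accuracy=0.7)
        assert report.overall_disconnection == 0.7

    def test_empty_bins_absent(self):
        records = [self._record(2, 2, True, True), self._record(6, 6, False, True)]
        report = rt.stratify(records)
        assert set(report.disconnection_by_input_tags) == {2, 6}
        assert 4 not in report.disconnection_by_input_tags

    def test_overall_is_count_weighted_mean(self):
        records = [self._record(2, 2, True, True)] * 8 + [self._record(3, 3, False, False)] * 2
        report = rt.stratify(records)
        bins = report.disconnection_by_input_tags
        weighted = sum(b.count * b.accuracy for b in bins.values()) / sum(
            b.count for b in bins.values()
        )
        assert report.overall_disconnection == pytest.approx(weighted) == 0.8

    def test_order_invariance(self, fixture_set, oracle, forward, mapper):
        fixtures = fixture_set[:20]
        inputs, results = _eval_inputs(fixtures), _oracle_results(fixtures, oracle)
        records, _ = rt.evaluate_all(inputs, results, forward, mapper)
        shuffled = records[:]
        random.Random(0).shuffle(shuffled)
        assert rt.stratify(shuffled) == rt.stratify(records)

    def test_invalid_records_excluded_from_bins(self):
        records = [
            self._record(2, 2, True, True),
            EvalRecord(
                n_tags_input=2, n_tags_predicted=0, round_trip=False,
                disconnection_match=False, gt_match_all=False,
                gt_match_mapped_only=False, valid=False,
            ),
        ]
        report = rt.stratify(records)
        assert report.n_records == 2 and report.n_valid == 1
        assert report.disconnection_by_input_tags[2].count == 1

    def test_report_frame_shape(self, fixture_set, oracle, forward, mapper):
        fixtures = fixture_set[:10]
        _, report = rt.evaluate_all(
            _eval_inputs(fixtures), _oracle_results(fixtures, oracle), forward, mapper
        )
        frame = report.to_frame()
        assert list(frame.columns) == ["metric", "n_tags", "count", "accuracy"]
        assert (frame["accuracy"] <= 1.0).all() and (frame["accuracy"] >= 0.0).all()
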