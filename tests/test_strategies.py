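"""Strategy predictions, candidate spaces, classification and tallies."""

import pytest

from bayesgaze.scenario import Answer, InferenceQuery
from bayesgaze.strategies import (
    BAYESIAN_STRATEGY_NAMES,
    Classification,
    ClassifierConfig,
    Strategy,
    StrategyError,
    candidate_space,
    classify_answer,
    predict_answer,
    separability_report,
    strategy_applicable,
    tally_errors,
)

PROB = "probability"
FREQ = "natural_frequency"


def q(code, fmt, ctx="mammography"):
    return InferenceQuery(code, fmt, ctx)


class TestPredictAnswer:
    @pytest.mark.parametrize("name,ctx,code,expected_pct", [
        ("fisherian", "mammography", "P(notA|notB)", 90.4),
        ("joint_occurrence", "economics", "P(notA|notB)", 45.0),
        ("likelihood_subtraction", "mammography", "P(A|B)", 70.4),
        ("base_rate_only", "mammography", "P(A|B)", 1.0),
        ("evidence_only", "mammography", "P(notA|notB)", 89.7),
        ("likelihood_addition", "mammography", "P(A|B)", 89.6),
    ])
    def test_probability_predictions(self, scenarios, name, ctx, code,
                                     expected_pct):
        ans = predict_answer(Strategy(name), scenarios[ctx],
                             q(code, PROB, ctx))
        assert ans.percent == expected_pct

    @pytest.mark.parametrize("name,code,pair", [
        ("joint_occurrence", "P(notA|B)", (950, 10_000)),
        ("pre_bayes", "P(A|B)", (100, 1030)),
        ("fisherian", "P(notA|B)", (950, 9900)),
        ("evidence_only", "P(A|B)", (1030, 10_000)),
        ("base_rate_only", "P(A|B)", (100, 10_000)),
    ])
    def test_frequency_predictions(self, mammography, name, code, pair):
        ans = predict_answer(Strategy(name), mammography, q(code, FREQ))
        assert (ans.numerator, ans.denominator) == pair

    def test_pre_bayes_has_no_probability_form(self, mammography):
        with pytest.raises(StrategyError):
            predict_answer(Strategy("pre_bayes"), mammography,
                           q("P(A|B)", PROB))

    def test_probability_only_strategies_reject_frequency(self, mammography):
        for name in ("likelihood_subtraction", "likelihood_addition",
                     "cpr_fpr_ratio"):
            with pytest.raises(StrategyError):
                predict_answer(Strategy(name), mammography,
                               q("P(A|B)", FREQ))

    def test_composite_strategies_need_bayesian_query(self, mammography):
        with pytest.raises(StrategyError):
            predict_answer(Strategy("fisherian"), mammography,
                           q("P(B|A)", PROB))

    def test_quantity_confusion_applies_to_any_query(self, mammography):
        ans = predict_answer(Strategy("quantity_confusion",
                                      quantity="P(B|A)"),
                             mammography, q("P(A&B)", PROB))
        assert ans.percent == 80.0

    def test_likelihood_addition_conjoint_variant(self, mammography):
        ans = predict_answer(Strategy("likelihood_addition"), mammography,
                             q("P(A|B)", PROB),
                             likelihood_addition_mode="conjoint")
        # conjoint variant adds the two cells of the conditioning column,
        # i.e. coincides with the evidence margin
        assert ans.percent == 10.3

    def test_cpr_fpr_ratio_capped_at_one(self, economics):
        ans = predict_answer(Strategy("cpr_fpr_ratio"), economics,
                             q("P(notA|notB)", PROB, "economics"))
        assert ans.value == 1.0


class TestCandidateSpace:
    def test_correct_prediction_always_present(self, scenarios, cfg):
        for ctx, s in scenarios.items():
            for code, fmt in [("P(A|B)", PROB), ("P(notB)", FREQ),
                              ("P(A&B)", PROB), ("P(B|A)", FREQ)]:
                cands = candidate_space(s, q(code, fmt, ctx), cfg)
                labels = {l for c in cands for l in c.labels}
                assert "correct" in labels

    def test_reference_class_variants_for_conjoint_frequency(
            self, mammography, cfg):
        cands = candidate_space(mammography, q("P(A&notB)", FREQ), cfg)
        by_pair = {(c.answer.numerator, c.answer.denominator): c.labels
                   for c in cands}
        assert "correct" in by_pair[(20, 10_000)]
        # "20 out of 100" is the natural-conditioning confusion P(notB|A)
        assert any("P(notB|A)" in l for l in by_pair[(20, 100)])

    def test_quantity_confusion_covers_conjoint_conditional_mixup(
            self, mammography, cfg):
        cands = candidate_space(mammography, q("P(A&B)", PROB), cfg)
        eighty = [c for c in cands if abs(c.answer.value - 0.80) < 1e-9]
        assert eighty and any("P(B|A)" in l for l in eighty[0].labels)

    def test_duplicates_are_collapsed(self, economics, cfg):
        cands = candidate_space(economics,
                                q("P(notA|notB)", PROB, "economics"), cfg)
        keys = [round(c.answer.value, 10) for c in cands]
        assert len(keys) == len(set(keys))

    def test_tolerance_monotonicity(self, mammography):
        query = q("P(notA|notB)", PROB)
        answer = Answer.probability(0.90)
        sets = []
        for tol in (0.0, 0.5, 2.0, 5.0):
            cfg = ClassifierConfig(probability_tolerance=tol)
            cls = classify_answer(answer, mammography, query, cfg)
            sets.append({l for l, _ in cls.candidates})
        for small, big in zip(sets, sets[1:]):
            assert small <= big


class TestClassifyAnswer:
    def test_joint_occurrence_from_marginal_frequency(self, mammography,
                                                      cfg):
        cls = classify_answer(Answer.frequency(950, 10_000), mammography,
                              q("P(notA|B)", FREQ), cfg)
        assert cls.assigned == "joint_occurrence"

    def test_one_percent_interval_accepts_7_5(self, mammography, cfg):
        cls = classify_answer(Answer.probability(0.075), mammography,
                              q("P(A|B)", PROB), cfg)
        assert cls.assigned == "correct"
        assert not cls.ambiguous

    def test_exact_correct_answer(self, economics, cfg):
        cls = classify_answer(Answer.probability(0.90), economics,
                              q("P(notA|notB)", PROB, "economics"), cfg)
        assert cls.assigned == "correct"

    def test_misread_family_for_conditional_frequency(self, mammography,
                                                      cfg):
        cls = classify_answer(Answer.frequency(20, 100), mammography,
                              q("P(notA|B)", FREQ), cfg)
        labels = {l for l, _ in cls.candidates}
        assert any(l.startswith("complement_misread") for l in labels)
        assert any("P(notB|A)" in l for l in labels)

    def test_unmatched_answer_is_unclassified(self, mammography, cfg):
        cls = classify_answer(Answer.probability(0.3456), mammography,
                              q("P(A|B)", PROB), cfg)
        assert cls.assigned == "unclassified"
        assert not cls.candidates

    def test_format_mismatch_rejected(self, mammography, cfg):
        with pytest.raises(StrategyError):
            classify_answer(Answer.probability(0.5), mammography,
                            q("P(A|B)", FREQ), cfg)

    @pytest.mark.parametrize("ctx", ["mammography", "economics"])
    @pytest.mark.parametrize("fmt", [PROB, FREQ])
    @pytest.mark.parametrize("code", ["P(A|B)", "P(notA|B)", "P(A|notB)",
                                      "P(notA|notB)"])
    def test_round_trip_recovery(self, scenarios, cfg, ctx, fmt, code):
        """Every noise-free prediction is recovered in its candidate set."""
        s = scenarios[ctx]
        query = q(code, fmt, ctx)
        for name in BAYESIAN_STRATEGY_NAMES:
            if not strategy_applicable(name, fmt):
                continue
            pred = predict_answer(Strategy(name), s, query)
            cls = classify_answer(pred, s, query, cfg)
            assert name in {l for l, _ in cls.candidates}

    def test_colliding_strategies_are_flagged_ambiguous(self, mammography,
                                                        cfg):
        # fisherian (90.4%) and evidence_only (89.7%) both round to 90%
        pred = predict_answer(Strategy("fisherian"), mammography,
                              q("P(notA|notB)", PROB))
        cls = classify_answer(pred, mammography, q("P(notA|notB)", PROB),
                              cfg)
        labels = {l for l, _ in cls.candidates}
        assert {"fisherian", "evidence_only"} <= labels
        assert cls.ambiguous

    def test_ratio_equivalent_mode_matches_reduced_pairs(self, economics):
        cfg = ClassifierConfig(frequency_match_mode="ratio_equivalent")
        cls = classify_answer(Answer.frequency(3, 5), economics,
                              q("P(notA|B)", FREQ, "economics"), cfg)
        assert "correct" in {l for l, _ in cls.candidates}


class TestSeparability:
    def test_report_lists_known_collision(self, mammography, cfg):
        queries = [q("P(notA|notB)", PROB)]
        rep = separability_report(mammography, queries, cfg)
        pairs = set(map(tuple, rep[["strategy_a", "strategy_b"]].values))
        assert ("evidence_only", "fisherian") in pairs

    def test_separable_trio_has_no_collision(self, economics, cfg):
        rep = separability_report(
            economics, [q("P(A|B)", PROB, "economics")], cfg)
        trio = {"correct", "joint_occurrence", "fisherian"}
        pairs = {frozenset(p) for p in
                 rep[["strategy_a", "strategy_b"]].values}
        assert not any(set(p) <= trio for p in pairs)


class TestTallyErrors:
    @staticmethod
    def _record(vis, fmt, assigned):
        cls = Classification(assigned=assigned, candidates=((assigned, 0.0),),
                             ambiguous=False, misread_flag=False)
        return {"visualization": vis, "format": fmt, "classification": cls}

    def test_all_correct_gives_empty_tally(self):
        recs = [self._record("tree", PROB, "correct") for _ in range(10)]
        tally = tally_errors(recs)
        assert tally.empty

    def test_injected_counts_and_conservation(self):
        recs = (
            [self._record("tree", PROB, "fisherian")] * 5
            + [self._record("tree", PROB, "joint_occurrence")] * 3
            + [self._record("tree", PROB, "unclassified")] * 2
            + [self._record("tree", PROB, "correct")] * 7)
        tally = tally_errors(recs).set_index("strategy")["count"]
        assert tally["fisherian"] == 5
        assert tally["joint_occurrence"] == 3
        assert tally["established_subtotal"] == 8
        assert tally["total_errors"] == 10  # = all incorrect trials
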