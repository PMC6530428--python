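"""Scenario engine: cells, the 16 probabilities, frequency trees, answers."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from bayesgaze.scenario import (
    ALL_QUANTITY_CODES,
    Answer,
    InferenceQuery,
    Scenario,
    ScenarioError,
    UndefinedConditionalError,
    answer_query,
    branch_probabilities,
    build_from_branches,
    enumerate_design_queries,
    format_percent,
    frequency_tree,
    parse_quantity,
    probability_set,
    scenario_from_dict,
    scenario_to_dict,
)

# random but valid branch parameterizations
branch_params = st.tuples(
    st.floats(0.001, 0.999), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
    st.integers(1, 10_000_000))


def _scenario(base, hit, fa, n=10_000):
    return build_from_branches(base, hit, fa, n)


class TestBuildFromBranches:
    @pytest.mark.parametrize("params,cells", [
        ((0.01, 0.80, 0.096, 10_000), (0.008, 0.002, 0.09504, 0.89496)),
        ((0.5, 1.0, 0.0, 100), (0.5, 0.0, 0.0, 0.5)),
        ((0.25, 0.80, 0.40, 1000), (0.20, 0.05, 0.30, 0.45)),
    ])
    def test_cells(self, params, cells):
        s = build_from_branches(*params)
        assert (s.p11, s.p10, s.p01, s.p00) == \
            pytest.approx(cells, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        (-0.1, 0.5, 0.5, 10), (0.5, 1.5, 0.5, 10), (0.5, 0.5, -1e-9, 10)])
    def test_rate_out_of_range(self, bad):
        with pytest.raises(ScenarioError):
            build_from_branches(*bad)

    def test_population_must_be_positive_integer(self):
        with pytest.raises(ScenarioError):
            build_from_branches(0.5, 0.5, 0.5, 0)

    @settings(derandomize=True, max_examples=200)
    @given(branch_params)
    def test_round_trip_through_branches(self, params):
        s = build_from_branches(*params)
        bp = branch_probabilities(s)
        s2 = build_from_branches(bp.b, bp.d, bp.f, s.population_n)
        for a, b in zip((s.p11, s.p10, s.p01, s.p00),
                        (s2.p11, s2.p10, s2.p01, s2.p00)):
            assert a == pytest.approx(b, abs=1e-12)


class TestProbabilitySet:
    def test_all_sixteen_defined_for_mammography(self, mammography):
        ps = probability_set(mammography)
        assert len(ps.values) == 16
        assert not ps.undefined

    def test_mammography_key_values(self, mammography):
        ps = probability_set(mammography)
        assert format_percent(ps["P(B)"]) == 10.3
        assert format_percent(ps["P(notA|notB)"]) == 99.8

    def test_independent_scenario_conditionals_equal_marginals(self):
        s = Scenario("ind", "A", "B", 0.25, 0.25, 0.25, 0.25, 100)
        ps = probability_set(s)
        for code in ("P(B|A)", "P(B|notA)", "P(A|B)", "P(A|notB)"):
            assert ps[code] == pytest.approx(0.5)

    def test_zero_margin_flags_conditionals_undefined(self):
        s = build_from_branches(0.0, 0.5, 0.2, 100)  # P(A) = 0
        ps = probability_set(s)
        assert "P(B|A)" in ps.undefined
        with pytest.raises(UndefinedConditionalError):
            ps["P(B|A)"]

    @settings(derandomize=True, max_examples=200)
    @given(branch_params)
    def test_complements_and_total_probability(self, params):
        ps = probability_set(build_from_branches(*params))
        assert ps["P(A)"] + ps["P(notA)"] == pytest.approx(1, abs=1e-12)
        assert ps["P(B)"] + ps["P(notB)"] == pytest.approx(1, abs=1e-12)
        # law of total probability for both marginals
        assert ps["P(B)"] == pytest.approx(
            ps["P(A&B)"] + ps["P(notA&B)"], abs=1e-12)
        assert ps["P(A)"] == pytest.approx(
            ps["P(A&B)"] + ps["P(A&notB)"], abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(branch_params)
    def test_bayes_identity_from_branches(self, params):
        """Bayes' rule from branch labels equals the cell-ratio route."""
        s = build_from_branches(*params)
        bp = branch_probabilities(s)
        for code in ("P(A|B)", "P(notA|B)", "P(A|notB)", "P(notA|notB)"):
            try:
                expected = s.value(code)
            except UndefinedConditionalError:
                continue
            assert bp.posterior(code) == pytest.approx(expected, abs=1e-10)


class TestFrequencyTree:
    def test_mammography_counts(self, mammography):
        t = frequency_tree(mammography)
        assert (t.A, t.B, t.C, t.D, t.E, t.F, t.G) == \
            (10_000, 100, 9_900, 80, 20, 950, 8_950)

    def test_economics_counts(self, economics):
        t = frequency_tree(economics)
        assert (t.A, t.B, t.C, t.D, t.E, t.F, t.G) == \
            (1_000, 250, 750, 200, 50, 300, 450)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.001, 0.999), st.floats(0, 1), st.floats(0, 1))
    def test_degenerate_population_of_one(self, base, hit, fa):
        t = frequency_tree(build_from_branches(base, hit, fa, 1))
        assert t.A == 1
        assert {t.B, t.C, t.D, t.E, t.F, t.G} <= {0, 1}

    @settings(derandomize=True, max_examples=200)
    @given(branch_params)
    def test_additivity(self, params):
        t = frequency_tree(build_from_branches(*params))
        assert t.B + t.C == t.A
        assert t.D + t.E == t.B
        assert t.F + t.G == t.C


class TestAnswerQuery:
    @pytest.mark.parametrize("ctx,code,expected_pct", [
        ("mammography", "P(A|B)", 7.8),
        ("mammography", "P(notA|notB)", 99.8),
        ("economics", "P(notA|notB)", 90.0),
        ("mammography", "P(B)", 10.3),
    ])
    def test_probability_answers(self, scenarios, ctx, code, expected_pct):
        ans = answer_query(scenarios[ctx],
                           InferenceQuery(code, "probability", ctx))
        assert ans.percent == expected_pct

    @pytest.mark.parametrize("ctx,code,pair", [
        ("mammography", "P(A|B)", (80, 1030)),
        ("mammography", "P(notB)", (8970, 10_000)),
        ("mammography", "P(notA|B)", (950, 1030)),
        ("economics", "P(notA|B)", (300, 500)),
        ("economics", "P(A&B)", (200, 1000)),
    ])
    def test_frequency_answers(self, scenarios, ctx, code, pair):
        ans = answer_query(scenarios[ctx],
                           InferenceQuery(code, "natural_frequency", ctx))
        assert (ans.numerator, ans.denominator) == pair

    def test_undefined_conditional_raises(self):
        s = build_from_branches(0.0, 0.5, 0.2, 100)
        with pytest.raises(UndefinedConditionalError):
            answer_query(s, InferenceQuery("P(B|A)", "probability", "x"))

    @settings(derandomize=True, max_examples=100)
    @given(branch_params)
    def test_format_consistency(self, params):
        """Frequency-pair ratio tracks the exact probability within the
        integer-rounding bound 2/N."""
        s = build_from_branches(*params)
        for code in ALL_QUANTITY_CODES:
            q_prob = InferenceQuery(code, "probability", "x")
            q_freq = InferenceQuery(code, "natural_frequency", "x")
            try:
                p = answer_query(s, q_prob).value
                f = answer_query(s, q_freq)
            except UndefinedConditionalError:
                continue
            bound = 2.0 / f.denominator + 2.0 / s.population_n
            assert abs(f.as_ratio - p) <= bound

    def test_complement_answers_sum_to_conditioning_set(self, mammography):
        for fmt in ("probability", "natural_frequency"):
            a = answer_query(mammography,
                             InferenceQuery("P(A|B)", fmt, "m"))
            b = answer_query(mammography,
                             InferenceQuery("P(notA|B)", fmt, "m"))
            if fmt == "probability":
                assert a.value + b.value == pytest.approx(1.0, abs=1e-12)
            else:
                assert a.numerator + b.numerator == a.denominator
                assert a.denominator == b.denominator


class TestQuantityCodes:
    @pytest.mark.parametrize("code,klass", [
        ("P(A)", "marginal"), ("P(notB)", "marginal"),
        ("P(A&B)", "conjoint"), ("P(notA&notB)", "conjoint"),
        ("P(B|A)", "conditional"), ("P(notB|notA)", "conditional"),
        ("P(A|B)", "bayesian"), ("P(notA|notB)", "bayesian"),
    ])
    def test_inference_class_follows_conditioning_direction(self, code,
                                                            klass):
        assert parse_quantity(code).inference_class == klass

    @pytest.mark.parametrize("bad", ["P(A&A)", "P(B|notB)", "Q(A)", "P(C)",
                                     "P(A&B|C)"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ScenarioError):
            parse_quantity(bad)

    def test_conjoint_canonical_order(self):
        assert parse_quantity("P(B&A)").code == "P(A&B)"


class TestDesignQueries:
    def test_ten_queries_with_class_counts(self):
        queries = enumerate_design_queries("mammography")
        assert len(queries) == 10
        classes = [q.inference_class for q in queries]
        assert classes.count("marginal") == 2
        assert classes.count("conjoint") == 2
        assert classes.count("conditional") == 2
        assert classes.count("bayesian") == 4
        bayes_codes = {q.quantity_code for q in queries
                       if q.inference_class == "bayesian"}
        assert bayes_codes == {"P(A|B)", "P(notA|B)", "P(A|notB)",
                               "P(notA|notB)"}

    def test_format_balance(self):
        for ctx in ("mammography", "economics"):
            queries = enumerate_design_queries(ctx)
            fmts = [q.format for q in queries]
            assert fmts.count("probability") == 5
            # non-Bayesian pairs split one probability / one frequency
            for klass in ("marginal", "conjoint", "conditional"):
                pair = [q.format for q in queries
                        if q.inference_class == klass]
                assert sorted(pair) == ["natural_frequency", "probability"]

    def test_unknown_context_rejected(self):
        with pytest.raises(ScenarioError):
            enumerate_design_queries("astrology")


class TestSerialization:
    def test_dict_round_trip(self, economics):
        s2 = scenario_from_dict(scenario_to_dict(economics))
        assert s2 == economics

    def test_answer_validation(self):
        with pytest.raises(ScenarioError):
            Answer.probability(1.5)
        with pytest.raises(ScenarioError):
            Answer.frequency(3, 0)
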