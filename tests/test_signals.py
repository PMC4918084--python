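import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from litsignal import (
    ContingencyTable,
    ValidationError,
    adjusted_pvalues,
    build_abstraction_level,
    build_reference_stats,
    build_set_of_interest,
    conditional_p,
    detect_signals,
    extract_candidate_pairs,
    hypergeom_upper_tail,
    prr,
)
from litsignal.corpus import ReferenceStats
from litsignal.candidates import SetOfInterest
from litsignal.abstraction import CoverageReport

from oracles import hypergeom_tail_oracle


class TestHypergeomUpperTail:
    def test_zero_observed_gives_one(self):
        assert hypergeom_upper_tail(n=100, a=10, s=5, m=0) == 1.0

    def test_worked_example_matches_enumeration(self):
        expected = hypergeom_tail_oracle(20, 5, 5, 2)
        assert hypergeom_upper_tail(n=20, a=5, s=5, m=2) == pytest.approx(
            expected, abs=1e-15
        )
        assert expected == pytest.approx(0.3661, abs=5e-5)

    def test_saturated_overlap_equals_closed_form(self):
        # m = s = a <= n reduces to C(a, s) / C(n, s)
        from math import comb

        assert hypergeom_upper_tail(n=12, a=4, s=4, m=4) == pytest.approx(
            comb(4, 4) / comb(12, 4), abs=1e-15
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=10, a=11, s=5, m=0),
            dict(n=10, a=5, s=11, m=0),
            dict(n=10, a=5, s=5, m=6),
            dict(n=-1, a=0, s=0, m=0),
        ],
    )
    def test_bounds_are_validated(self, kwargs):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(**kwargs)

    def test_agrees_with_scipy_survival(self):
        for n, a, s, m in [(50, 12, 9, 4), (200, 30, 25, 10), (1000, 40, 60, 7)]:
            assert hypergeom_upper_tail(n, a, s, m) == pytest.approx(
                float(scipy_hypergeom.sf(m - 1, n, a, s)), rel=1e-10
            )

    @given(
        n=st.integers(1, 30),
        data=st.data(),
    )
    def test_in_unit_interval_and_monotone_in_m(self, n, data):
        a = data.draw(st.integers(0, n))
        s = data.draw(st.integers(0, n))
        previous = 1.0
        for m in range(0, min(a, s) + 1):
            p = hypergeom_upper_tail(n, a, s, m)
            assert 0 < p <= 1
            assert p <= previous + 1e-15
            previous = p


class TestConditionalP:
    def test_zero_joint_count_gives_one(self):
        assert conditional_p(a_y=10, a_xy=3, o=4, m_xy=0) == 1.0

    def test_structural_identity_with_plain_tail(self):
        assert conditional_p(a_y=20, a_xy=5, o=5, m_xy=2) == hypergeom_upper_tail(
            n=20, a=5, s=5, m=2
        )

    def test_ancestor_containment_makes_joint_counts_unsurprising(self):
        # y ancestor of x in the reference: a_xy == a_x, every x-article is a
        # y-article, so observing all of y's set-of-interest articles with x
        # barely surprises; enumerate on a 30-article reference
        a_y, a_x = 12, 12
        p = conditional_p(a_y=a_y, a_xy=a_x, o=5, m_xy=5)
        assert p == 1.0
        p_partial = conditional_p(a_y=30, a_xy=12, o=5, m_xy=2)
        assert p_partial == pytest.approx(hypergeom_tail_oracle(30, 12, 5, 2), abs=1e-15)
        assert p_partial > 0.5

    def test_empty_conditioning_population_rejected(self):
        with pytest.raises(ValidationError):
            conditional_p(a_y=0, a_xy=1, o=0, m_xy=0)
        with pytest.raises(ValidationError):
            conditional_p(a_y=5, a_xy=0, o=2, m_xy=0)


def _soi(subject, rep_articles):
    articles = frozenset().union(*rep_articles.values()) if rep_articles else frozenset()
    return SetOfInterest(
        subject=subject,
        articles=articles,
        rep_articles={t: frozenset(a) for t, a in rep_articles.items()},
        coverage=CoverageReport(frozenset(rep_articles), frozenset()),
    )


class TestAdjustedPvalues:
    def test_single_enriched_term_keeps_raw(self):
        stats = ReferenceStats(n=100, term_counts={"x": 10}, cofreq={})
        soi = _soi("drug", {"x": {"a1", "a2"}})
        assert adjusted_pvalues({"x": 0.01}, stats, soi) == {"x": 0.01}

    def test_terms_never_cooccurring_keep_raw(self):
        stats = ReferenceStats(n=100, term_counts={"x": 10, "y": 10}, cofreq={})
        soi = _soi("drug", {"x": {"a1"}, "y": {"a2"}})
        adjusted = adjusted_pvalues({"x": 0.01, "y": 0.02}, stats, soi)
        assert adjusted == {"x": 0.01, "y": 0.02}

    def test_adjusted_never_below_raw(self):
        stats = ReferenceStats(
            n=100, term_counts={"x": 10, "y": 20}, cofreq={("x", "y"): 8}
        )
        soi = _soi("drug", {"x": {"a1", "a2"}, "y": {"a1", "a2", "a3"}})
        raw = {"x": 0.01, "y": 0.003}
        adjusted = adjusted_pvalues(raw, stats, soi)
        for term in raw:
            assert adjusted[term] >= raw[term]


class TestParentChildSuppression:
    """Hand-built corpus where the specific child term drives the signal and
    the general parent is co-annotated along with it."""

    @pytest.fixture(scope="class")
    def results(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        results = detect_signals("DX001", pairs, corpus, stats, level, method="gea")
        return {r.term: r for r in results}

    def test_reference_margins_are_as_designed(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        assert stats.n == 60
        assert stats.count("X0001") == 6
        assert stats.count("P0001") == 20
        assert stats.cofreq_count("X0001", "P0001") == 6

    def test_both_terms_raw_enriched(self, results):
        # frozen via the enumeration oracle on the designed margins
        assert results["X0001"].raw_p == pytest.approx(
            hypergeom_tail_oracle(60, 6, 5, 4), abs=1e-15
        )
        assert results["P0001"].raw_p == pytest.approx(
            hypergeom_tail_oracle(60, 20, 5, 5), abs=1e-15
        )
        assert results["X0001"].raw_p < 0.005
        assert results["P0001"].raw_p < 0.005

    def test_child_survives_conditioning_on_parent(self, results):
        expected = hypergeom_tail_oracle(20, 6, 5, 4)  # population: parent articles
        assert results["X0001"].adjusted_p == pytest.approx(expected, abs=1e-15)
        assert results["X0001"].adjusted_p < 0.05

    def test_redundant_parent_suppressed(self, results):
        # all child articles are parent articles: conditional p is exactly 1
        assert results["P0001"].adjusted_p == 1.0
        assert results["P0001"].adjusted_p > 0.05

    def test_ranking_puts_child_first(self, results):
        ordered = sorted(results.values(), key=lambda r: (r.adjusted_p, r.term))
        assert ordered[0].term == "X0001"


class TestPrr:
    def test_equal_rates_give_unity(self):
        value, lo, hi = prr(ContingencyTable(5, 45, 10, 90))
        assert value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_worked_example(self):
        value, _, _ = prr(ContingencyTable(5, 95, 10, 890))
        assert value == pytest.approx(4.5)

    def test_zero_cell_correction(self):
        value, lo, hi = prr(ContingencyTable(2, 8, 0, 90))
        # corrected table (2.5, 8.5, 0.5, 90.5)
        expected = (2.5 / 11.0) / (0.5 / 91.0)
        assert value == pytest.approx(expected)
        assert expected == pytest.approx(41.36, abs=5e-3)
        assert lo < value < hi

    @given(
        a=st.integers(1, 50),
        b=st.integers(1, 50),
        c=st.integers(1, 50),
        d=st.integers(1, 50),
        k=st.integers(2, 10),
    )
    def test_scale_invariance_and_ci_narrows(self, a, b, c, d, k):
        base, lo, hi = prr(ContingencyTable(a, b, c, d))
        scaled, slo, shi = prr(ContingencyTable(k * a, k * b, k * c, k * d))
        assert scaled == pytest.approx(base, rel=1e-12)
        assert slo >= lo - 1e-12 and shi <= hi + 1e-12

    def test_negative_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 2, 3, 4)


class TestDetectSignals:
    def test_subject_without_articles_yields_no_signals(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        assert detect_signals("NOPE", pairs, corpus, stats, level) == []

    def test_unknown_method_rejected(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        with pytest.raises(ValidationError):
            detect_signals("DX001", pairs, corpus, stats, level, method="ror")

    def test_prr_on_parent_child_fixture(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        results = detect_signals("DX001", pairs, corpus, stats, level, method="prr")
        by_term = {r.term: r for r in results}
        # candidate universe is the drug's own 5 articles here, so the
        # "without drug" margin is empty and the zero-cell correction engages
        assert by_term["X0001"].m == 4
        assert all(r.ci_low <= r.prr <= r.ci_high for r in results)

    def test_threshold_sweep_is_monotone(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        results = detect_signals("DX001", pairs, corpus, stats, level)
        counts = [
            sum(r.adjusted_p < t for r in results) for t in (0.1, 0.05, 0.005)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_adjusted_at_least_raw_everywhere(self, parent_child_study):
        terminology, corpus = parent_child_study
        stats = build_reference_stats(corpus, terminology)
        level = build_abstraction_level(terminology, stats.ic, 0.0, 10.0)
        pairs = extract_candidate_pairs(corpus)
        for result in detect_signals("DX001", pairs, corpus, stats, level):
            assert result.adjusted_p >= result.raw_p
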