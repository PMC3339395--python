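"""Query parsing, segment scoring, object aggregation, ranking, profiles."""

import pytest

from boss import indexer, search
from boss.errors import EmptyQueryError, ObjectNotFoundError
from boss.search import (
    ObjectResult,
    Query,
    QueryTerm,
    ScoringConfig,
    aggregate_objects,
    coord,
    match_segments,
    object_profile,
    parse_query,
    rank_objects,
    recency,
    run_query,
    score_segment,
)
from conftest import build_random_index, brute_force_ranking


def make_query(*terms, query_time=None):
    return Query(
        raw=" ".join(terms),
        terms=[QueryTerm(t, frozenset({t})) for t in terms],
        query_time=query_time,
    )


class TestParseQuery:
    def test_nominal_relation_term_gains_lemma_alternate(self, feature_lexicon):
        query = parse_query("EGFR inhibitors", lexicon=feature_lexicon)
        assert [t.text for t in query.terms] == ["egfr", "inhibitors"]
        assert query.terms[1].alternates == {"inhibitors", "inhibit"}

    def test_all_stopword_query_rejected(self, feature_lexicon):
        with pytest.raises(EmptyQueryError):
            parse_query("the of", lexicon=feature_lexicon)

    def test_three_content_terms_survive(self, feature_lexicon):
        query = parse_query("oral corticosteroids increase", lexicon=feature_lexicon)
        assert len(query.terms) == 3

    def test_quoted_phrase_becomes_joined_term(self, feature_lexicon):
        query = parse_query('"oral corticosteroids" increase', lexicon=feature_lexicon)
        assert query.terms[0].alternates == {"oral_corticosteroids"}
        assert len(query.terms) == 2


class TestCoord:
    def test_full_overlap(self):
        q = make_query("a", "b")
        assert coord(q, frozenset({"a", "b", "c"})) == 1.0

    def test_partial_overlap_is_a_fraction(self):
        q = make_query("a", "b", "c")
        assert coord(q, frozenset({"a", "b"})) == pytest.approx(2 / 3)

    def test_no_overlap(self):
        q = make_query("a", "b")
        assert coord(q, frozenset({"x"})) == 0.0

    def test_alternates_of_one_term_count_once(self):
        q = Query("i", [QueryTerm("inhibitors", frozenset({"inhibitors", "inhibit"}))])
        assert coord(q, frozenset({"inhibit", "inhibitors"})) == 1.0


class TestRecency:
    @pytest.mark.parametrize("delta, expected", [(0, 1.0), (10, 0.5), (20, 0.25)])
    def test_half_life_values(self, delta, expected):
        config = ScoringConfig(recency_half_life=10)
        assert recency(2000, 2000 + delta, config) == pytest.approx(expected)

    def test_future_publication_clamps_to_one(self):
        assert recency(2020, 2010, ScoringConfig()) == 1.0

    def test_unknown_year_is_neutral(self):
        assert recency(None, 2010, ScoringConfig()) == 1.0

    def test_strictly_decreasing_in_age(self):
        config = ScoringConfig(recency_half_life=7)
        values = [recency(2000, 2000 + d, config) for d in range(0, 30, 3)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestScoreSegment:
    def test_product_of_four_factors(self, example2_index):
        # coord 1, one feature w=1, two objects w=1, rc=1 -> 2.0
        record = example2_index.segments["d2:0:0"]
        q = make_query("oral", "decrease", query_time=2011)
        hit = score_segment(q, record, ScoringConfig(), example2_index, 2011)
        assert hit.coord == 1.0 and hit.feature_sum == 1.0
        assert hit.object_sum == 2.0 and hit.rc == 1.0
        assert hit.score == 2.0

    def test_zero_coord_annihilates(self, example2_index):
        record = example2_index.segments["d2:0:0"]
        q = make_query("zzz", query_time=2011)
        hit = score_segment(q, record, ScoringConfig(), example2_index, 2011)
        assert hit.score == 0.0

    def test_empty_feature_policy(self, paper_bundle, feature_lexicon):
        corpus = [{"id": "d", "year": 2011, "text": "STAT3 plays a role in cancer."}]
        index = indexer.build_index(corpus, paper_bundle.dictionary, feature_lexicon)
        (record,) = index.segments.values()
        assert record.feature_ids == ()
        q = make_query("stat3", query_time=2011)
        lenient = score_segment(q, record, ScoringConfig(), index, 2011)
        assert lenient.score == 1.0
        literal = score_segment(
            q, record, ScoringConfig(empty_feature_policy="zero"), index, 2011
        )
        assert literal.score == 0.0

    def test_feature_and_object_weights_enter_the_sums(self, example2_index):
        config = ScoringConfig(
            feature_weights={"DECREASE": 0.5},
            object_weights={"O_CCCHEM": 2.0},
        )
        record = example2_index.segments["d2:0:0"]
        q = make_query("decrease", query_time=2011)
        hit = score_segment(q, record, config, example2_index, 2011)
        assert hit.feature_sum == 0.5
        assert hit.object_sum == 3.0  # O_CORT 1.0 + O_CCCHEM 2.0


class TestMatchSegments:
    def test_full_context_outranks_partial(self, example2_index, feature_lexicon):
        query = parse_query("oral corticosteroids increase", lexicon=feature_lexicon)
        hits = match_segments(example2_index, query)
        assert len(hits) == 2
        by_id = {h.segment_id: h for h in hits}
        assert by_id["d2:0:1"].coord == 1.0
        assert by_id["d2:0:0"].coord == pytest.approx(2 / 3)

    def test_exact_context_excludes_partial_matches(
        self, example2_index, feature_lexicon
    ):
        query = parse_query("oral corticosteroids increase", lexicon=feature_lexicon)
        hits = match_segments(example2_index, query, exact_context=True)
        assert [h.segment_id for h in hits] == ["d2:0:1"]

    def test_terms_split_across_segments_return_nothing_in_exact_mode(
        self, example2_index, feature_lexicon
    ):
        query = parse_query("decrease IL-8", lexicon=feature_lexicon)
        assert match_segments(example2_index, query, exact_context=True) == []
        # both keywords do occur somewhere in the sentence
        assert len(match_segments(example2_index, query)) == 2

    def test_absent_term_returns_empty(self, example2_index, feature_lexicon):
        query = parse_query("cetuximab", lexicon=feature_lexicon)
        assert match_segments(example2_index, query) == []


class TestAggregateAndRank:
    def test_scores_sum_over_contributing_segments(self, feature_lexicon):
        _, _, _, dictionary, index = build_random_index(21, feature_lexicon)
        query = make_query(
            next(iter(index.postings)), query_time=2011
        )
        hits = match_segments(index, query)
        results = aggregate_objects(hits, index)
        for result in results:
            contributing = [
                h.score
                for h in hits
                if result.object_id in index.segments[h.segment_id].object_ids
            ]
            assert result.score == pytest.approx(sum(contributing))
            assert result.mention_count == len(contributing)
            assert result.mention_count >= result.article_count >= 1

    def test_segment_score_counted_once_per_object(self, example2_index):
        # one segment holding two objects credits its full score to both
        q = make_query("decrease", query_time=2011)
        hits = match_segments(example2_index, q)
        assert len(hits) == 1
        results = {r.object_id: r for r in aggregate_objects(hits, example2_index)}
        assert set(results) == {"O_CORT", "O_CCCHEM"}
        assert results["O_CORT"].score == results["O_CCCHEM"].score == hits[0].score

    def test_conservation_of_score_mass(self, feature_lexicon):
        _, _, _, _, index = build_random_index(22, feature_lexicon)
        term = next(iter(index.postings))
        hits = match_segments(index, make_query(term, query_time=2011))
        results = aggregate_objects(hits, index)
        lhs = sum(r.score for r in results)
        rhs = sum(
            h.score * len(index.segments[h.segment_id].object_ids) for h in hits
        )
        assert lhs == pytest.approx(rhs)

    def test_no_hits_no_results(self, example2_index):
        assert aggregate_objects([], example2_index) == []

    def test_rank_by_score_then_mentions_then_id(self):
        results = [
            ObjectResult("B", 1.0, 5, 2, []),
            ObjectResult("A", 2.0, 1, 1, []),
            ObjectResult("C", 1.0, 3, 2, []),
            ObjectResult("D", 1.0, 5, 3, []),
        ]
        ranked = rank_objects(results)
        assert [r.object_id for r in ranked] == ["A", "B", "D", "C"]

    def test_snippets_capped_at_five(self, feature_lexicon):
        spec_seed = 23
        _, _, _, dictionary, index = build_random_index(spec_seed, feature_lexicon)
        for term in index.postings:
            hits = match_segments(index, make_query(term, query_time=2011))
            for result in aggregate_objects(hits, index):
                assert len(result.snippets) <= 5
                assert len(result.snippets) == min(5, result.mention_count)

    def test_adding_a_matching_segment_never_lowers_an_object_score(
        self, paper_bundle, feature_lexicon
    ):
        corpus = [{"id": "d1", "year": 2011, "text": "STAT3 binds EGFR."}]
        more = corpus + [{"id": "d2", "year": 2011, "text": "TNF activates STAT3."}]
        dictionary = paper_bundle.dictionary
        from boss.lexicon import ObjectDictionary, ObjectEntry

        dictionary = ObjectDictionary([
            ObjectEntry("O_STAT3", "STAT3", object_type="protein"),
            ObjectEntry("O_EGFR", "EGFR", object_type="protein"),
            ObjectEntry("O_TNF", "TNF", object_type="protein"),
        ])
        small = indexer.build_index(corpus, dictionary, feature_lexicon)
        large = indexer.build_index(more, dictionary, feature_lexicon)
        for idx in (small, large):
            pass
        score_small = {
            r.object_id: r.score for r in run_query(small, "STAT3", query_time=2011)
        }
        score_large = {
            r.object_id: r.score for r in run_query(large, "STAT3", query_time=2011)
        }
        assert score_large["O_STAT3"] >= score_small["O_STAT3"]


class TestOracleEquivalence:
    """Index-probing retrieval equals a direct scan of every segment."""

    @pytest.mark.parametrize("seed", [31, 32, 33, 34])
    @pytest.mark.parametrize("exact", [False, True])
    def test_random_corpora_and_queries(self, feature_lexicon, seed, exact):
        spec, _, truth, dictionary, index = build_random_index(seed, feature_lexicon)
        queries = [
            f"{subject} {lemma}" for (subject, lemma, _o) in truth.triple_segments
        ] + [spec.objects[0], "zzz unknown"]
        for raw in queries:
            try:
                query = parse_query(raw, query_time=2012, lexicon=feature_lexicon)
            except EmptyQueryError:
                continue
            hits = match_segments(index, query, exact_context=exact)
            got = [
                (r.object_id, r.score, r.mention_count, r.article_count)
                for r in rank_objects(aggregate_objects(hits, index))
            ]
            expected = brute_force_ranking(index, query, exact_context=exact)
            assert got == expected, raw

    def test_deterministic_ranked_output(self, feature_lexicon):
        _, _, _, _, index = build_random_index(35, feature_lexicon)
        term = next(iter(index.postings))
        runs = [
            [
                (r.object_id, r.score, r.mention_count, r.article_count, r.snippets)
                for r in run_query(index, term, query_time=2012)
            ]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_invariant_ranges(self, feature_lexicon):
        _, _, _, _, index = build_random_index(36, feature_lexicon)
        for term in list(index.postings)[:50]:
            hits = match_segments(index, make_query(term, query_time=2012))
            for hit in hits:
                assert 0.0 <= hit.coord <= 1.0
                assert 0.0 < hit.rc <= 1.0
                assert hit.score >= 0.0


@pytest.fixture(scope="module")
def toy_index(feature_lexicon):
    from boss.lexicon import ObjectDictionary, ObjectEntry

    dictionary = ObjectDictionary([
        ObjectEntry("X", "CSF3", object_type="protein"),
        ObjectEntry("Y", "LIF", object_type="protein"),
        ObjectEntry("Z", "cytarabine", object_type="drug"),
    ])
    corpus = [
        {"id": "a", "year": 2009, "text": "CSF3 activates LIF."},
        {"id": "b", "year": 2010, "text": "CSF3 binds LIF."},
        {"id": "c", "year": 2010, "text": "CSF3 inhibits cytarabine."},
    ]
    return indexer.build_index(corpus, dictionary, feature_lexicon)


class TestObjectProfile:
    def test_co_occurrence_counts(self, toy_index):
        profile = object_profile(toy_index, "X")
        assert profile.co_objects == [("Y", 2), ("Z", 1)]
        assert profile.segment_count == 3
        assert profile.article_count == 3

    def test_interaction_cloud(self, toy_index):
        profile = object_profile(toy_index, "X")
        assert dict(profile.interactions) == {"activate": 1, "bind": 1, "inhibit": 1}

    def test_per_year_article_counts(self, toy_index):
        profile = object_profile(toy_index, "X")
        assert profile.per_year == {2009: 1, 2010: 2}

    def test_co_object_filter(self, toy_index):
        profile = object_profile(toy_index, "X", co_object="Y")
        assert profile.segment_count == 2
        assert profile.per_year == {2009: 1, 2010: 1}

    def test_interaction_filter(self, toy_index, feature_lexicon):
        profile = object_profile(toy_index, "X", feature="bind")
        assert profile.segment_count == 1
        assert profile.co_objects == [("Y", 1)]

    def test_context_restriction(self, toy_index, feature_lexicon):
        context = parse_query("cytarabine", lexicon=feature_lexicon)
        profile = object_profile(toy_index, "X", context=context)
        assert profile.segment_count == 1
        assert profile.co_objects == [("Z", 1)]

    def test_object_with_no_matching_context_is_empty_not_error(
        self, toy_index, feature_lexicon
    ):
        context = parse_query("unrelated", lexicon=feature_lexicon)
        profile = object_profile(toy_index, "Y", context=context)
        assert profile.segment_count == 0
        assert profile.co_objects == [] and profile.per_year == {}

    def test_unknown_object_is_an_error(self, toy_index):
        with pytest.raises(ObjectNotFoundError):
            object_profile(toy_index, "NOPE")
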