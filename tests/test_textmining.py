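"""Dictionary tagging, weighted co-mention counting, scoring and calibration."""

from __future__ import annotations

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subcell.errors import CalibrationError, ValidationError
from subcell.ontology import OntologyGraph
from subcell.records import DocumentRecord
from subcell.textmining import (
    Lexicon,
    PairCounts,
    ScoringParams,
    build_lexicon,
    calibrate_z,
    count_pairs,
    score_all,
    score_pair,
    stars_from_z,
    tag,
)

Z80 = 0.8416212335729143  # Phi^-1(0.8)


@pytest.fixture
def mini_ontology():
    return OntologyGraph(
        terms={"C:1", "C:2", "C:3"},
        names={"C:1": "nucleus", "C:2": "Golgi apparatus", "C:3": "Golgi"},
        edges={("C:3", "C:2", "is_a")},
    )


class TestBuildLexicon:
    def test_protein_name_colliding_with_compartment_discarded(self, mini_ontology):
        lex = build_lexicon({"membrane": "P1", "ABC1": "P2"},
                            OntologyGraph(terms={"C:9"}, names={"C:9": "membrane"}, edges=set()))
        assert "membrane" in lex.entries and lex.entries["membrane"][1] == "compartment"
        assert lex.entries["abc1"] == ("P2", "protein", "all")

    def test_frequent_name_blocked(self, mini_ontology):
        lex = build_lexicon(
            {"CAG": "P1", "ABC1": "P2"}, mini_ontology,
            match_counts={"CAG": 2500}, block_threshold=2000,
        )
        assert "cag" in lex.blocked and "cag" not in lex.entries
        assert "abc1" in lex.entries

    def test_empty_protein_map_rejected(self, mini_ontology):
        with pytest.raises(ValidationError):
            build_lexicon({}, mini_ontology)


def _doc(*sentences):
    return DocumentRecord(doc_id="d", sentences=tuple(sentences))


class TestTag:
    def test_protein_and_compartment_in_one_sentence(self, mini_ontology):
        lex = build_lexicon({"P53": "P53ID"}, mini_ontology)
        matches = tag(_doc("P53 localizes to the nucleus"), lex)
        assert [(m.sentence, m.entity, m.kind) for m in matches] == [
            (0, "P53ID", "protein"),
            (0, "C:1", "compartment"),
        ]

    def test_blocked_name_never_emitted(self, mini_ontology):
        lex = build_lexicon(
            {"CAG": "P1"}, mini_ontology, match_counts={"CAG": 9999}, block_threshold=10
        )
        assert tag(_doc("CAG repeats and CAG again"), lex) == []

    def test_longest_match_wins_on_overlap(self, mini_ontology):
        lex = build_lexicon({"ABC1": "P1"}, mini_ontology)
        matches = tag(_doc("located in the Golgi apparatus lumen"), lex)
        assert [(m.entity,) for m in matches] == [("C:2",)]

    def test_case_insensitive_token_boundaries(self, mini_ontology):
        lex = build_lexicon({"ABC1": "P1"}, mini_ontology)
        assert tag(_doc("NUCLEUS staining"), lex)[0].entity == "C:1"
        # substring inside a longer token must not match
        assert tag(_doc("pronucleuses are different"), lex) == []

    def test_matches_exhaustive_span_enumeration(self, mini_ontology):
        """Oracle: enumerate all token-boundary occurrences, resolve
        leftmost-longest, compare with the matcher on random sentences."""
        lex = build_lexicon({"ABC1": "P1", "XY": "P2"}, mini_ontology)
        names = {**{n: e for n, (e, k, _) in lex.entries.items()}}
        rng = np.random.default_rng(11)
        vocabulary = ["abc1", "xy", "golgi", "apparatus", "golgi apparatus",
                      "nucleus", "the", "in", "protein"]
        for _ in range(200):
            words = [vocabulary[int(rng.integers(len(vocabulary)))] for _ in range(8)]
            text = " ".join(words)
            # oracle: all candidate spans via regex with word boundaries
            spans = []
            for name, entity in names.items():
                for m in re.finditer(rf"\b{re.escape(name)}\b", text, re.IGNORECASE):
                    spans.append((m.start(), m.end(), entity))
            spans.sort(key=lambda s: (s[0], -(s[1] - s[0])))
            resolved, cursor = [], 0
            for start, end, entity in spans:
                if start >= cursor:
                    resolved.append((start, end, entity))
                    cursor = end
            got = [(m.start, m.end, m.entity) for m in tag(_doc(text), lex)]
            assert got == resolved


class TestCountPairs:
    def test_same_sentence_gets_both_weights(self, mini_ontology):
        lex = build_lexicon({"P53": "P"}, mini_ontology)
        doc = _doc("P53 sits in the nucleus")
        counts = count_pairs([(doc, tag(doc, lex))], ScoringParams(w_sentence=2.0, w_abstract=1.0))
        assert counts.c_pl[("P", "C:1")] == 3.0

    def test_different_sentences_get_abstract_weight_only(self, mini_ontology):
        lex = build_lexicon({"P53": "P"}, mini_ontology)
        doc = _doc("P53 was studied", "staining of the nucleus")
        counts = count_pairs([(doc, tag(doc, lex))])
        assert counts.c_pl[("P", "C:1")] == 1.0

    def test_repeated_mention_in_one_abstract_counts_once(self, mini_ontology):
        lex = build_lexicon({"P53": "P"}, mini_ontology)
        doc = _doc("P53 and P53 again in the nucleus", "nucleus once more")
        counts = count_pairs([(doc, tag(doc, lex))])
        assert counts.c_pl[("P", "C:1")] == 3.0  # per-abstract deltas, not per-mention

    def test_contributions_sum_over_abstracts(self, mini_ontology):
        lex = build_lexicon({"P53": "P"}, mini_ontology)
        d1 = _doc("P53 in the nucleus")
        d2 = _doc("P53 alone", "the nucleus alone")
        counts = count_pairs([(d1, tag(d1, lex)), (d2, tag(d2, lex))])
        assert counts.c_pl[("P", "C:1")] == 4.0
        counts.validate()

    @given(seed=st.integers(0, 500))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_marginal_consistency_on_random_corpora(self, seed):
        counts = _random_counts(seed)
        counts.validate()


def _random_tagged_corpus(seed, n_docs=None):
    rng = np.random.default_rng(seed)
    graph = OntologyGraph(
        terms={"L:1", "L:2"}, names={"L:1": "nucleus", "L:2": "cytosol"}, edges=set()
    )
    lex = build_lexicon({"AAA": "P1", "BBB": "P2", "CCC": "P3"}, graph)
    words = ["AAA", "BBB", "CCC", "nucleus", "cytosol", "filler", "study"]
    docs = []
    for d in range(n_docs or int(rng.integers(1, 21))):
        sentences = tuple(
            " ".join(words[int(rng.integers(len(words)))] for _ in range(4))
            for _ in range(int(rng.integers(1, 4)))
        )
        doc = DocumentRecord(doc_id=f"d{d}", sentences=sentences)
        docs.append((doc, tag(doc, lex)))
    return docs


def _random_counts(seed):
    return count_pairs(_random_tagged_corpus(seed))


class TestScorePair:
    PARAMS = ScoringParams(alpha=0.6)

    def test_single_pair_corpus(self):
        counts = PairCounts(c_pl={("P", "L"): 4.0}, c_p={"P": 4.0}, c_l={"L": 4.0}, c_total=4.0)
        assert score_pair(counts, "P", "L", self.PARAMS) == pytest.approx(4**0.6, abs=1e-9)

    def test_alpha_one_returns_raw_count(self):
        counts = PairCounts(
            c_pl={("P", "L"): 3.0, ("Q", "L"): 1.0},
            c_p={"P": 3.0, "Q": 1.0}, c_l={"L": 4.0}, c_total=4.0,
        )
        assert score_pair(counts, "P", "L", ScoringParams(alpha=1.0)) == pytest.approx(3.0)

    def test_two_protein_fixture(self):
        counts = PairCounts(
            c_pl={("P1", "L"): 3.0, ("P2", "L"): 1.0},
            c_p={"P1": 3.0, "P2": 1.0}, c_l={"L": 4.0}, c_total=4.0,
        )
        # ratio = 3*4/(3*4) = 1, so S = 3^0.6
        assert score_pair(counts, "P1", "L", self.PARAMS) == pytest.approx(3**0.6, abs=1e-9)

    def test_zero_count_rejected(self):
        counts = PairCounts(c_pl={("P", "L"): 1.0}, c_p={"P": 1.0}, c_l={"L": 1.0}, c_total=1.0)
        with pytest.raises(ValidationError):
            score_pair(counts, "P", "M", self.PARAMS)

    def test_monotone_in_pair_count_at_fixed_marginals(self):
        base = dict(c_p={"P": 50.0}, c_l={"L": 50.0}, c_total=200.0)
        scores = [
            score_pair(PairCounts(c_pl={("P", "L"): c}, **base), "P", "L", self.PARAMS)
            for c in (1.0, 2.0, 5.0, 10.0, 25.0)
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_recomputation(self, seed):
        """S from the pipeline equals a direct loop over the raw tagged corpus."""
        docs = _random_tagged_corpus(seed)
        params = ScoringParams()
        counts = count_pairs(docs, params)
        if not counts.c_pl:
            return
        # brute force: per abstract, explicit delta evaluation
        brute: dict = {}
        for doc, matches in docs:
            proteins = {m.entity for m in matches if m.kind == "protein"}
            comps = {m.entity for m in matches if m.kind == "compartment"}
            for p in proteins:
                for l in comps:
                    same = any(
                        any(m.entity == p and m.sentence == s for m in matches)
                        and any(m.entity == l and m.sentence == s for m in matches)
                        for s in range(len(doc.sentences))
                    )
                    brute[(p, l)] = brute.get((p, l), 0.0) + params.w_abstract + (
                        params.w_sentence if same else 0.0
                    )
        assert brute == pytest.approx(counts.c_pl)
        total = sum(brute.values())
        for (p, l), c in brute.items():
            cp = sum(v for (pp, _), v in brute.items() if pp == p)
            cl = sum(v for (_, ll), v in brute.items() if ll == l)
            expected = c**0.6 * (c * total / (cp * cl)) ** 0.4
            assert score_pair(counts, p, l, params) == pytest.approx(expected, rel=1e-12)


class TestCalibration:
    def test_decile_fixture(self):
        mu, sigma = calibrate_z(list(range(10)))
        assert mu == pytest.approx(3.6)
        assert sigma == pytest.approx(1.8 / Z80, rel=1e-6)
        assert (9 - mu) / sigma == pytest.approx(5.4 / (1.8 / Z80), rel=1e-6)

    def test_location_shift_leaves_z_unchanged(self):
        scores = [0.5, 1.0, 2.5, 4.0, 7.0, 9.5]
        mu0, sigma0 = calibrate_z(scores)
        mu1, sigma1 = calibrate_z([s + 11.0 for s in scores])
        assert sigma1 == pytest.approx(sigma0)
        z0 = [(s - mu0) / sigma0 for s in scores]
        z1 = [(s + 11.0 - mu1) / sigma1 for s in scores]
        assert z1 == pytest.approx(z0)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_z([2.0] * 10)

    def test_too_few_distinct_scores_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_z([1.0, 2.0, 3.0, 3.0, 3.0])


class TestStarsFromZ:
    @pytest.mark.parametrize(("z", "stars"), [(20.0, 4.0), (4.0, 2.0), (-1.0, 0.0), (8.0, 4.0)])
    def test_examples(self, z, stars):
        assert stars_from_z(z) == stars

    @given(z=st.floats(-50, 50, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_clamped_to_unit_interval_of_stars(self, z):
        assert 0.0 <= stars_from_z(z) <= 4.0


class TestScoreAll:
    def test_stars_monotone_in_score(self):
        counts = _random_counts(7)
        scored = score_all(counts)
        by_score = sorted(scored, key=lambda s: s.score)
        stars = [s.stars for s in by_score]
        assert stars == sorted(stars)
        assert all(0 <= s.stars <= 4 for s in scored)
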