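"""Properties of the synthetic world, corpus, annotations and predictions."""

from __future__ import annotations

import numpy as np
import pytest

from subcell.channels import knowledge_records
from subcell.ontology import load_obo
from subcell.synthetic import (
    AMBIGUOUS_ALIAS,
    CONFLICTING_ALIAS,
    PROMISCUOUS_ALIAS,
    WorldConfig,
    build_world_lexicon,
    generate_annotations,
    generate_corpus,
    generate_predictions,
    generate_world,
    synth_all,
    write_obo,
)
from subcell.textmining import tag


def _world(**kw):
    return generate_world(WorldConfig(n_proteins=kw.pop("n_proteins", 300), seed=kw.pop("seed", 1), **kw))


class TestGenerateWorld:
    def test_same_seed_identical_world(self):
        w1, w2 = _world(), _world()
        assert w1.truth == w2.truth
        assert w1.alias_rows == w2.alias_rows

    def test_distinct_seeds_differ(self):
        assert _world(seed=1).truth != _world(seed=2).truth

    def test_every_protein_has_a_compartment(self):
        assert all(len(terms) >= 1 for terms in _world().truth.values())

    def test_single_localization_when_rate_zero(self):
        world = generate_world(
            WorldConfig(n_proteins=300, multi_loc_rate=0.0, co_loc_pairs=(), seed=3)
        )
        assert all(len(terms) == 1 for terms in world.truth.values())

    def test_unplanted_co_membership_matches_model_baseline(self):
        """Without planting, every pair's co-membership sits within 3 SD of
        the membership model's own baseline (one compartment, plus a second
        uniform one with probability multi_loc_rate)."""
        m = 0.3
        world = generate_world(
            WorldConfig(n_proteins=2000, multi_loc_rate=m, co_loc_pairs=(), seed=5)
        )
        n = len(world.truth)
        k = len(world.slim)
        expected = 2 * m / k**2  # P(primary=A, extra=B) + P(primary=B, extra=A)
        sd = (expected * (1 - expected) / n) ** 0.5
        labels = sorted(world.label_to_term)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert abs(world.co_membership_rate(a, b) - expected) <= 3 * sd

    def test_planted_pairs_exceed_unplanted_baseline(self, default_world):
        unplanted = generate_world(
            WorldConfig(
                n_proteins=default_world.config.n_proteins,
                co_loc_pairs=(),
                seed=default_world.config.seed,
            )
        )
        n = len(default_world.truth)
        for a, b, excess in default_world.config.co_loc_pairs:
            baseline = unplanted.co_membership_rate(a, b)
            planted = default_world.co_membership_rate(a, b)
            assert planted > baseline + 3 * np.sqrt(baseline * (1 - baseline) / n)

    def test_toy_ontology_has_children_per_slim_term(self):
        world = _world()
        for term in world.slim.slim_terms:
            assert len(world.child_terms[term]) >= 2
            for child in world.child_terms[term]:
                assert term in world.ontology.ancestors(child)


class TestLexiconHygiene:
    def test_conflicting_alias_discarded(self):
        lex = build_world_lexicon(_world())
        assert lex.entries.get(CONFLICTING_ALIAS, (None, None, None))[1] == "compartment"

    def test_promiscuous_alias_blocked(self):
        lex = build_world_lexicon(_world())
        assert PROMISCUOUS_ALIAS.lower() in lex.blocked

    def test_ambiguous_alias_in_table_twice(self):
        world = _world()
        canonicals = world.alias_table.resolve("9606", AMBIGUOUS_ALIAS)
        assert len(canonicals) == 2


class TestGenerateCorpus:
    def test_zero_noise_yields_only_true_pairs(self):
        world = generate_world(
            WorldConfig(n_proteins=100, confounder_rate=0.0, seed=4)
        )
        docs = generate_corpus(world, n_abstracts=800, noise_rate=0.0, seed=5)
        lex = build_world_lexicon(world)
        slim_terms = set(world.slim.slim_terms)
        for doc in docs:
            matches = tag(doc, lex)
            proteins = {m.entity for m in matches if m.kind == "protein"}
            for m in matches:
                if m.kind != "compartment":
                    continue
                slim_hits = world.ontology.ancestors(m.entity) & slim_terms
                for p in proteins:
                    assert slim_hits <= world.truth[p]

    def test_same_sentence_rate_one_co_mentions_in_sentence(self):
        world = generate_world(WorldConfig(n_proteins=50, confounder_rate=0.0, seed=6))
        docs = generate_corpus(
            world, n_abstracts=200, same_sentence_rate=1.0, noise_rate=0.0, seed=7
        )
        lex = build_world_lexicon(world)
        from subcell.textmining import ScoringParams, count_pairs

        tagged = [(doc, tag(doc, lex)) for doc in docs]
        params = ScoringParams(w_sentence=2.0, w_abstract=1.0)
        counts = count_pairs(tagged, params)
        assert counts.c_pl  # co-mentions exist
        # every abstract-level contribution is w_s + w_a = 3, so every pair
        # count is a multiple of 3
        for value in counts.c_pl.values():
            assert value % 3.0 == 0.0

    def test_deterministic_under_seed(self):
        world = _world()
        d1 = generate_corpus(world, n_abstracts=50, seed=9)
        d2 = generate_corpus(world, n_abstracts=50, seed=9)
        assert d1 == d2


class TestGenerateAnnotations:
    def test_full_coverage_full_five_star_covers_truth(self):
        world = generate_world(WorldConfig(n_proteins=50, seed=8))
        annotations, _ = generate_annotations(world, coverage=1.0, five_star_rate=1.0, seed=9)
        records = knowledge_records(annotations)
        assert all(r.stars == 5.0 for r in records)
        # every truth pair has an annotation at the term or a descendant
        annotated = set()
        for rec in records:
            accession_index = int(rec.protein[2:])
            pid = world.protein_ids[accession_index]
            slim_hits = world.ontology.ancestors(rec.term) & set(world.slim.slim_terms)
            annotated.update((pid, t) for t in slim_hits)
        truth_pairs = {(p, t) for p, terms in world.truth.items() for t in terms}
        assert annotated == truth_pairs

    def test_zero_coverage_empty(self):
        world = generate_world(WorldConfig(n_proteins=50, seed=8))
        annotations, _ = generate_annotations(world, coverage=0.0, seed=9)
        assert annotations == []

    def test_five_star_fraction_within_binomial_error(self):
        world = generate_world(WorldConfig(n_proteins=2000, seed=10))
        rate = 0.5
        annotations, _ = generate_annotations(world, coverage=1.0, five_star_rate=rate, seed=11)
        records = knowledge_records(annotations)
        n = len(records)
        observed = sum(1 for r in records if r.stars == 5.0) / n
        sd = (rate * (1 - rate) / n) ** 0.5
        assert abs(observed - rate) <= 3 * sd


class TestGeneratePredictions:
    def test_posteriors_pile_up_near_zero_and_one(self):
        world = _world()
        _, yloc_rows = generate_predictions(world, seed=12)
        p = np.array([row[2] for row in yloc_rows])
        extreme = ((p <= 0.1) | (p >= 0.9)).mean()
        assert extreme >= 0.8

    def test_psort_scores_within_k(self):
        world = _world()
        psort_rows, _ = generate_predictions(world, seed=12)
        assert all(0 <= v <= k for _, _, v, k in psort_rows)

    def test_chance_accuracy_is_uninformative(self):
        """At accuracy 1/|slim| the top predictions hit truth at chance rate."""
        world = generate_world(WorldConfig(n_proteins=1000, co_loc_pairs=(), seed=13))
        psort_rows, _ = generate_predictions(world, accuracy=1 / 11, seed=14)
        tops = {}
        for pid, label, v, k in psort_rows:
            if pid not in tops or v > tops[pid][1]:
                tops[pid] = (label, v)
        hits = sum(
            1 for pid, (label, _) in tops.items()
            if world.label_to_term[label] in world.truth[pid]
        )
        rate = hits / len(tops)
        # truth membership covers ~1.3 of 11 compartments per protein
        assert rate < 0.35


class TestRoundTrips:
    def test_obo_roundtrip_preserves_traversal_structure(self, tmp_path):
        world = _world()
        path = tmp_path / "toy.obo"
        write_obo(world, path)
        graph = load_obo(path)
        assert world.ontology.terms <= graph.terms
        for term in world.ontology.terms:
            assert graph.ancestors(term) & world.ontology.terms == world.ontology.ancestors(term)
        assert "TOY:9002" in graph.obsolete
        assert {rel for _, _, rel in graph.edges} <= {"is_a", "part_of"}

    def test_synth_all_files_feed_every_reader(self, tmp_path):
        from subcell.channels import import_gaf, import_hpa_tsv, read_location_map
        from subcell.ontology import load_slim
        from subcell.predictions import import_predictions_tsv
        from subcell.textmining import read_corpus, read_lexicon_tsv
        from subcell.unify import read_alias_tsv

        manifest = synth_all(WorldConfig(n_proteins=60, seed=15), tmp_path / "fix")
        graph = load_obo(manifest["obo"])
        slim = load_slim(manifest["slim"], "animal")
        slim.validate_against(graph)
        location_map = read_location_map(manifest["location_map"])
        assert import_gaf(manifest["gaf"])
        records, _ = import_hpa_tsv(manifest["hpa"], location_map)
        assert all(r.channel == "experiments" for r in records)
        docs = read_corpus(manifest["corpus"])
        assert len(docs) == 20 * 60
        lexicon = read_lexicon_tsv(manifest["lexicon"])
        assert lexicon.entries
        assert read_alias_tsv(manifest["aliases"]).taxa() == {"9606"}
        psort, _ = import_predictions_tsv(manifest["psort"], "psort", location_map)
        yloc, _ = import_predictions_tsv(manifest["yloc"], "yloc", location_map)
        assert psort and yloc
        assert all(r.stars <= 3 for r in psort + yloc)
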