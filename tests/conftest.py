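"""Shared fixtures: toy ontologies and the default synthetic study."""

from __future__ import annotations

import pytest

from subcell.ontology import OntologyGraph, SlimSet
from subcell.pipeline import run_world
from subcell.synthetic import (
    WorldConfig,
    generate_annotations,
    generate_corpus,
    generate_predictions,
    generate_world,
)

# Seeds of the default study: world 7, corpus 8, annotations 9, predictions
# 10, permutations 11.  Fixed once; every stochastic assertion pins them.
WORLD_SEED = 7


def make_default_world(n_proteins: int = 2000, **overrides):
    config = WorldConfig(n_proteins=n_proteins, seed=WORLD_SEED, **overrides)
    return generate_world(config)


def run_default(world, n_perm: int = 10_000):
    docs = generate_corpus(world, seed=WORLD_SEED + 1)
    annotations, hpa = generate_annotations(world, seed=WORLD_SEED + 2)
    psort_rows, yloc_rows = generate_predictions(world, seed=WORLD_SEED + 3)
    return run_world(
        world, docs, annotations, hpa, psort_rows, yloc_rows,
        n_perm=n_perm, perm_seed=WORLD_SEED + 4,
    )


@pytest.fixture(scope="session")
def default_world():
    """The default planted world: 2,000 proteins, trafficking co-localization."""
    return make_default_world()


@pytest.fixture(scope="session")
def default_run(default_world):
    """Full pipeline result on the default world (10,000 permutations)."""
    return run_default(default_world)


@pytest.fixture(scope="session")
def small_world():
    """A 200-protein world for cheap structural checks."""
    return make_default_world(n_proteins=200)


@pytest.fixture(scope="session")
def small_run(small_world):
    return run_default(small_world, n_perm=500)


@pytest.fixture
def chain_graph():
    """child --is_a--> mid --part_of--> root, plus an isolated term."""
    return OntologyGraph(
        terms={"T:child", "T:mid", "T:root", "T:iso"},
        names={
            "T:child": "nucleolus",
            "T:mid": "nucleus",
            "T:root": "cell",
            "T:iso": "island",
        },
        edges={
            ("T:child", "T:mid", "is_a"),
            ("T:mid", "T:root", "part_of"),
        },
    )


@pytest.fixture
def toy_slim_graph():
    """A miniature two-compartment ontology for projection tests."""
    terms = {"S:root", "S:nucleus", "S:cytosol", "S:nucleolus", "S:ribosome", "S:orphan"}
    names = {
        "S:root": "cell",
        "S:nucleus": "nucleus",
        "S:cytosol": "cytosol",
        "S:nucleolus": "nucleolus",
        "S:ribosome": "ribosome",
        "S:orphan": "orphan body",
    }
    edges = {
        ("S:nucleus", "S:root", "is_a"),
        ("S:cytosol", "S:root", "is_a"),
        ("S:nucleolus", "S:nucleus", "part_of"),
        ("S:ribosome", "S:cytosol", "is_a"),
        ("S:orphan", "S:root", "is_a"),
    }
    return OntologyGraph(terms=terms, names=names, edges=edges)
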