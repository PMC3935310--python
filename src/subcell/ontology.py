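"""Cellular-component ontology handling and slim projection.

Fine-grained localization terms are projected ("backtracked") onto a small
set of labeled compartments — a slim of 11 broad terms for animal and fungal
cells, 12 for plants — by walking ``is_a`` and ``part_of`` edges up the
ontology.  When several pieces of evidence land on the same slim compartment,
the strongest (highest-star) one is kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet
import yaml

from .errors import InputError, TermLookupError, ValidationError
from .records import EvidenceRecord

logger = logging.getLogger(__name__)

#: Relations used for upward traversal; everything else is ignored.
TRAVERSAL_RELATIONS = frozenset({"is_a", "part_of"})

#: Compartment labels of the three slim presets.  The animal slim has a
#: lysosome where fungal and plant cells have a vacuole; the plant slim adds
#: the plastid for a total of 12 compartments.
SLIM_LABELS: dict[str, tuple[str, ...]] = {
    "animal": (
        "nucleus",
        "cytosol",
        "cytoskeleton",
        "peroxisome",
        "lysosome",
        "endoplasmic reticulum",
        "Golgi apparatus",
        "plasma membrane",
        "endosome",
        "extracellular space",
        "mitochondrion",
    ),
    "fungal": (
        "nucleus",
        "cytosol",
        "cytoskeleton",
        "peroxisome",
        "vacuole",
        "endoplasmic reticulum",
        "Golgi apparatus",
        "plasma membrane",
        "endosome",
        "extracellular space",
        "mitochondrion",
    ),
    "plant": (
        "nucleus",
        "cytosol",
        "cytoskeleton",
        "peroxisome",
        "vacuole",
        "endoplasmic reticulum",
        "Golgi apparatus",
        "plasma membrane",
        "endosome",
        "extracellular space",
        "mitochondrion",
        "plastid",
    ),
}

_SLIM_SIZES = {"animal": 11, "fungal": 11, "plant": 12}


@dataclass
class OntologyGraph:
    """Cellular-component terms with typed is_a/part_of parent edges."""

    terms: set[str]
    names: dict[str, str]
    edges: set[tuple[str, str, str]]  # (child, parent, relation)
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, relation in self.edges:
            if relation not in TRAVERSAL_RELATIONS:
                raise ValidationError(f"unsupported relation {relation!r}")
            if child not in self.terms or parent not in self.terms:
                raise ValidationError(
                    f"edge ({child}, {parent}) references unknown term"
                )
            self._parents[child].add(parent)
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise ValidationError(
                f"is_a/part_of closure contains a cycle through {member!r}"
            )

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def name(self, term: str) -> str:
        return self.names.get(term, term)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over is_a/part_of (includes *term*)."""
        if term not in self.terms:
            raise TermLookupError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        closure: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in closure:
                continue
            closure.add(t)
            stack.extend(self._parents.get(t, ()))
        result = frozenset(closure)
        self._ancestor_cache[term] = result
        return result

    def descendants_or_self(self, term: str) -> frozenset[str]:
        if term not in self.terms:
            raise TermLookupError(f"unknown term {term!r}")
        return frozenset(t for t in self.terms if term in self.ancestors(t))


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


@dataclass(frozen=True)
class SlimSet:
    """An ordered list of labeled compartment terms for one cell schema."""

    schema: str
    slim_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.schema not in _SLIM_SIZES:
            raise ValidationError(f"unknown slim schema {self.schema!r}")
        expected = _SLIM_SIZES[self.schema]
        if len(self.slim_terms) != expected:
            raise ValidationError(
                f"{self.schema} slim must have {expected} terms, "
                f"got {len(self.slim_terms)}"
            )
        if len(set(self.slim_terms)) != len(self.slim_terms):
            raise ValidationError("slim terms must be unique")

    def __iter__(self) -> Iterator[str]:
        return iter(self.slim_terms)

    def __len__(self) -> int:
        return len(self.slim_terms)

    def validate_against(self, graph: OntologyGraph) -> None:
        missing = [t for t in self.slim_terms if t not in graph]
        if missing:
            raise ValidationError(f"slim terms absent from ontology: {missing}")


def load_slim(path: str | Path, schema: str) -> SlimSet:
    """Read a slim preset file (YAML mapping of schema name -> term id list)."""
    with open(path) as fh:
        presets = yaml.safe_load(fh)
    if not isinstance(presets, Mapping) or schema not in presets:
        raise InputError(f"slim preset file {path} has no schema {schema!r}")
    return SlimSet(schema=schema, slim_terms=tuple(presets[schema]))


_OBSOLETE_RE = re.compile(r"^is_obsolete:\s*true", re.MULTILINE)


def _scan_obsolete_ids(path: str | Path) -> set[str]:
    """Collect ids of obsolete [Term] stanzas (obonet drops them silently)."""
    obsolete: set[str] = set()
    text = Path(path).read_text()
    for stanza in text.split("[Term]")[1:]:
        stanza = stanza.split("\n[", 1)[0]
        m = re.search(r"^id:\s*(\S+)", stanza, re.MULTILINE)
        if m and _OBSOLETE_RE.search(stanza):
            obsolete.add(m.group(1))
    return obsolete


def load_obo(
    path: str | Path, namespace: str | None = "cellular_component"
) -> OntologyGraph:
    """Load an OBO file into an :class:`OntologyGraph`.

    Only non-obsolete ``[Term]`` stanzas of the requested namespace are kept
    (terms without a namespace tag pass the filter, so toy ontologies work).
    ``is_a`` and ``relationship: part_of`` edges are captured; any other
    relationship is dropped.  Edges pointing outside the kept term set are
    dropped as well.
    """
    try:
        net = obonet.read_obo(path, ignore_obsolete=True)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read OBO file {path}: {exc}") from exc
    except Exception as exc:  # obonet raises assorted parse errors
        raise InputError(f"malformed OBO file {path}: {exc}") from exc

    def keep(node: str, data: Mapping) -> bool:
        ns = data.get("namespace")
        return namespace is None or ns is None or ns == namespace

    terms = {n for n, d in net.nodes(data=True) if keep(n, d)}
    names = {
        n: d.get("name", n) for n, d in net.nodes(data=True) if n in terms
    }
    edges: set[tuple[str, str, str]] = set()
    dropped_relations = 0
    for child, parent, relation in net.edges(keys=True):
        if relation not in TRAVERSAL_RELATIONS:
            dropped_relations += 1
            continue
        if child in terms and parent in terms:
            edges.add((child, parent, relation))
    if dropped_relations:
        logger.info("dropped %d non-traversal relationship edges", dropped_relations)

    obsolete = _scan_obsolete_ids(path)
    return OntologyGraph(terms=terms, names=names, edges=edges, obsolete=obsolete)


@dataclass
class BacktrackResult:
    """Slim-level records plus bookkeeping on what could not be projected."""

    records: list[EvidenceRecord]
    dropped_no_slim: int = 0
    unknown_terms: int = 0

    def __iter__(self) -> Iterator[EvidenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def backtrack(
    records: Iterable[EvidenceRecord],
    graph: OntologyGraph,
    slim: SlimSet,
) -> BacktrackResult:
    """Project evidence records onto the slim compartments.

    Each record yields one slim-level record per slim term among the
    ancestors of its term.  A record whose term has no slim ancestor is
    dropped (counted); an unknown term is skipped with a warning.  Per
    (protein, slim term, channel) the strongest evidence wins.
    """
    slim_terms = set(slim.slim_terms)
    best: dict[tuple[str, str, str], EvidenceRecord] = {}
    dropped = 0
    unknown = 0
    for rec in records:
        if rec.term in graph.obsolete:
            logger.warning("obsolete term %s: record skipped", rec.term)
            unknown += 1
            continue
        try:
            anc = graph.ancestors(rec.term)
        except TermLookupError:
            logger.warning("unknown term %s: record skipped", rec.term)
            unknown += 1
            continue
        hits = anc & slim_terms
        if not hits:
            dropped += 1
            continue
        for slim_term in hits:
            key = (rec.protein, slim_term, rec.channel)
            cur = best.get(key)
            if cur is None or rec.stars > cur.stars:
                best[key] = rec.with_term(slim_term)
    ordered = sorted(
        best.values(), key=lambda r: (r.protein, r.term, r.channel)
    )
    if dropped:
        logger.info("backtrack: %d records had no slim ancestor", dropped)
    return BacktrackResult(records=ordered, dropped_no_slim=dropped, unknown_terms=unknown)
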