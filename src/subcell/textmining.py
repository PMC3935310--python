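"""Literature co-mention channel: tagging, counting, scoring, calibration.

Proteins and compartment names are tagged in abstracts with an exact,
case-insensitive, token-boundary dictionary matcher.  Co-mentions accumulate
into a weighted count

    C(P, L) = sum_k ( w_s * delta_s^k + w_a * delta_a^k )

over abstracts *k*, where the deltas are 1 when protein P and localization L
are co-mentioned in the same sentence (delta_s) or the same abstract
(delta_a) and 0 otherwise.  The co-occurrence score mixes the raw count with
a marginal-normalised ratio,

    S(P, L) = C(P,L)^alpha * ( C(P,L) * C(.,.) / (C(P,.) * C(.,L)) )^(1-alpha)

with alpha = 0.6.  Because raw scores grow with the literature, they are
converted to z-scores against a Gaussian background whose mean is the 40th
percentile of the observed score distribution (the mode of the low-scoring
random component) and whose standard deviation is estimated from the spread
between the 20th and 40th percentiles.  Stars are z/2, clamped to [0, 4].
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import CalibrationError, InputError, ValidationError
from .ontology import OntologyGraph
from .records import DocumentRecord, EvidenceRecord

logger = logging.getLogger(__name__)

#: Phi^-1(0.8): the background Gaussian's 80th-percentile z, used to turn the
#: P40 - P20 spread into a standard deviation.
_Z80 = float(norm.ppf(0.8))


@dataclass(frozen=True)
class ScoringParams:
    """Weights and mixing exponent of the co-occurrence score."""

    w_sentence: float = 2.0
    w_abstract: float = 1.0
    alpha: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must lie in [0, 1]")
        if self.w_sentence < 0 or self.w_abstract < 0:
            raise ValidationError("weights must be non-negative")


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


@dataclass
class Lexicon:
    """Dictionary of taggable names: entity id, kind and organism per name."""

    entries: dict[str, tuple[str, str, str]]  # name -> (id, kind, organism)
    blocked: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.entries) & self.blocked
        if overlap:
            raise ValidationError(f"names both tagged and blocked: {sorted(overlap)[:3]}")


def build_lexicon(
    protein_names: Mapping[str, str],
    ontology: OntologyGraph,
    match_counts: Mapping[str, int] | None = None,
    block_threshold: int = 2000,
    compartment_synonyms: Mapping[str, str] | None = None,
    organism: str = "all",
) -> Lexicon:
    """Assemble the tagging dictionary from protein aliases and term labels.

    Protein names that collide (case-insensitively) with a compartment label
    are discarded outright; names occurring more than *block_threshold* times
    in the corpus are blocked — recognised but never emitted, mirroring the
    manual blocking of promiscuous acronyms.
    """
    if not protein_names:
        raise ValidationError("empty protein name map")
    entries: dict[str, tuple[str, str, str]] = {}
    for term in sorted(ontology.terms):
        if term in ontology.obsolete:
            continue
        entries[_normalize_name(ontology.name(term))] = (term, "compartment", "all")
    if compartment_synonyms:
        for syn, term in compartment_synonyms.items():
            entries[_normalize_name(syn)] = (term, "compartment", "all")
    compartment_labels = set(entries)

    counts = match_counts or {}
    blocked: set[str] = set()
    discarded = 0
    for name, pid in protein_names.items():
        norm_name = _normalize_name(name)
        if norm_name in compartment_labels:
            discarded += 1
            continue
        if counts.get(name, 0) > block_threshold:
            blocked.add(norm_name)
            continue
        entries[norm_name] = (pid, "protein", organism)
    for label in compartment_labels:
        if counts.get(label, 0) > block_threshold:
            del entries[label]
            blocked.add(label)
    if discarded:
        logger.info("discarded %d protein names colliding with compartment labels", discarded)
    return Lexicon(entries=entries, blocked=blocked)


@dataclass(frozen=True)
class Match:
    """One tagged mention: sentence index, character span, entity, kind."""

    sentence: int
    start: int
    end: int
    entity: str
    kind: str


_TOKEN_RE = re.compile(r"\w+")


class _Matcher:
    """Token-level multi-word dictionary matcher, longest match wins."""

    def __init__(self, lexicon: Lexicon) -> None:
        self._by_first: dict[str, list[tuple[tuple[str, ...], str | None, str | None]]] = {}
        for name, (entity, kind, _org) in lexicon.entries.items():
            toks = tuple(name.split(" "))
            self._by_first.setdefault(toks[0], []).append((toks, entity, kind))
        for name in lexicon.blocked:
            toks = tuple(name.split(" "))
            self._by_first.setdefault(toks[0], []).append((toks, None, None))
        for cands in self._by_first.values():
            cands.sort(key=lambda c: len(c[0]), reverse=True)

    def scan(self, sentence_index: int, text: str) -> list[Match]:
        tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
        matches: list[Match] = []
        i = 0
        while i < len(tokens):
            tok, start, _ = tokens[i]
            hit = None
            for name_toks, entity, kind in self._by_first.get(tok, ()):
                n = len(name_toks)
                if i + n <= len(tokens) and all(
                    tokens[i + j][0] == name_toks[j] for j in range(n)
                ):
                    hit = (n, entity, kind)
                    break  # candidates sorted longest-first
            if hit is None:
                i += 1
                continue
            n, entity, kind = hit
            if entity is not None:  # blocked names consume their span silently
                matches.append(
                    Match(
                        sentence=sentence_index,
                        start=start,
                        end=tokens[i + n - 1][2],
                        entity=entity,
                        kind=kind,  # type: ignore[arg-type]
                    )
                )
            i += n
        return matches


def tag(document: DocumentRecord, lexicon: Lexicon | _Matcher) -> list[Match]:
    """Tag one abstract; returns matches in sentence/position order."""
    matcher = lexicon if isinstance(lexicon, _Matcher) else _Matcher(lexicon)
    out: list[Match] = []
    for idx, sentence in enumerate(document.sentences):
        out.extend(matcher.scan(idx, sentence))
    return out


def compile_matcher(lexicon: Lexicon) -> _Matcher:
    """Pre-compile the lexicon for repeated tagging of a large corpus."""
    return _Matcher(lexicon)


@dataclass
class PairCounts:
    """Weighted co-mention counts C(P,L) with marginals and grand total."""

    c_pl: dict[tuple[str, str], float]
    c_p: dict[str, float]
    c_l: dict[str, float]
    c_total: float
    organism: str = "all"

    def validate(self, tol: float = 1e-9) -> None:
        sum_p: dict[str, float] = dict.fromkeys(self.c_p, 0.0)
        sum_l: dict[str, float] = dict.fromkeys(self.c_l, 0.0)
        for (p, l), v in self.c_pl.items():
            if v < 0:
                raise ValidationError(f"negative pair count for ({p}, {l})")
            sum_p[p] = sum_p.get(p, 0.0) + v
            sum_l[l] = sum_l.get(l, 0.0) + v
        for p, total in self.c_p.items():
            if abs(sum_p.get(p, 0.0) - total) > tol:
                raise ValidationError(f"protein marginal mismatch for {p}")
        for l, total in self.c_l.items():
            if abs(sum_l.get(l, 0.0) - total) > tol:
                raise ValidationError(f"compartment marginal mismatch for {l}")
        if abs(sum(self.c_pl.values()) - self.c_total) > tol:
            raise ValidationError("grand total mismatch")


def count_pairs(
    tagged_docs: Iterable[tuple[DocumentRecord, Sequence[Match]]],
    params: ScoringParams = ScoringParams(),
    organism: str = "all",
) -> PairCounts:
    """Accumulate weighted co-mention counts over abstracts.

    Per abstract, a (protein, compartment) pair mentioned anywhere in it
    contributes ``w_abstract``, plus ``w_sentence`` if some single sentence
    mentions both.  The deltas are per-abstract indicators: repeating a
    mention inside one abstract does not add weight.
    """
    c_pl: dict[tuple[str, str], float] = {}
    for doc, matches in tagged_docs:
        n_sent = len(doc.sentences)
        proteins: set[str] = set()
        compartments: set[str] = set()
        per_sentence: dict[int, tuple[set[str], set[str]]] = {}
        for m in matches:
            if not (0 <= m.sentence < n_sent):
                raise ValidationError(
                    f"match references sentence {m.sentence} of {doc.doc_id}"
                )
            ps, ls = per_sentence.setdefault(m.sentence, (set(), set()))
            if m.kind == "protein":
                proteins.add(m.entity)
                ps.add(m.entity)
            else:
                compartments.add(m.entity)
                ls.add(m.entity)
        if not proteins or not compartments:
            continue
        same_sentence: set[tuple[str, str]] = set()
        for ps, ls in per_sentence.values():
            same_sentence.update((p, l) for p in ps for l in ls)
        for p in proteins:
            for l in compartments:
                w = params.w_abstract + (
                    params.w_sentence if (p, l) in same_sentence else 0.0
                )
                c_pl[(p, l)] = c_pl.get((p, l), 0.0) + w

    c_p: dict[str, float] = {}
    c_l: dict[str, float] = {}
    for (p, l), v in c_pl.items():
        c_p[p] = c_p.get(p, 0.0) + v
        c_l[l] = c_l.get(l, 0.0) + v
    return PairCounts(
        c_pl=c_pl, c_p=c_p, c_l=c_l, c_total=sum(c_pl.values()), organism=organism
    )


def score_pair(
    counts: PairCounts,
    protein: str,
    compartment: str,
    params: ScoringParams = ScoringParams(),
) -> float:
    """Co-occurrence score S(P,L) = C^alpha * (C * C.. / (Cp. * C.l))^(1-alpha)."""
    c = counts.c_pl.get((protein, compartment), 0.0)
    if c <= 0:
        raise ValidationError(f"no co-mention count for ({protein}, {compartment})")
    cp = counts.c_p.get(protein, 0.0)
    cl = counts.c_l.get(compartment, 0.0)
    if cp <= 0 or cl <= 0:
        raise ValidationError("zero marginal with non-zero pair count")
    ratio = c * counts.c_total / (cp * cl)
    return c**params.alpha * ratio ** (1.0 - params.alpha)


def calibrate_z(scores: Sequence[float]) -> tuple[float, float]:
    """Fit the Gaussian background: mean = P40, sigma = (P40 - P20) / Phi^-1(0.8).

    Percentiles use linear interpolation between order statistics.  Requires
    at least five distinct scores and a positive spread.
    """
    arr = np.asarray(scores, dtype=float)
    if len(np.unique(arr)) < 5:
        raise CalibrationError("need at least 5 distinct scores to calibrate")
    p40 = float(np.percentile(arr, 40))
    p20 = float(np.percentile(arr, 20))
    sigma = (p40 - p20) / _Z80
    if sigma <= 0:
        raise CalibrationError("degenerate score distribution (sigma <= 0)")
    return p40, sigma


def stars_from_z(z: float) -> float:
    """Text-mining stars: z/2, clamped to [0, 4]."""
    return min(4.0, max(0.0, z / 2.0))


@dataclass(frozen=True)
class ScoredPair:
    """A scored (protein, compartment) co-mention with z and stars."""

    protein: str
    compartment: str
    count: float
    score: float
    z: float
    stars: float


def score_all(
    counts: PairCounts, params: ScoringParams = ScoringParams()
) -> list[ScoredPair]:
    """Score every counted pair, calibrate z against the score distribution."""
    pairs = sorted(counts.c_pl)
    scores = [score_pair(counts, p, l, params) for p, l in pairs]
    mu, sigma = calibrate_z(scores)
    out = []
    for (p, l), s in zip(pairs, scores):
        z = (s - mu) / sigma
        out.append(
            ScoredPair(
                protein=p,
                compartment=l,
                count=counts.c_pl[(p, l)],
                score=s,
                z=z,
                stars=stars_from_z(z),
            )
        )
    return out


def textmining_records(scored: Iterable[ScoredPair]) -> list[EvidenceRecord]:
    """Convert scored pairs into text-mining-channel evidence records."""
    return [
        EvidenceRecord(
            protein=sp.protein,
            term=sp.compartment,
            channel="textmining",
            source="textmining",
            stars=sp.stars,
            provenance=f"z={sp.z:.3f}",
        )
        for sp in scored
    ]


# ---------------------------------------------------------------------------
# I/O


def read_corpus(path: str | Path, sentence_delimiter: str = "|") -> list[DocumentRecord]:
    """Read abstracts: TSV (doc_id TAB delimited sentences) or JSON lines."""
    docs: list[DocumentRecord] = []
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot read corpus {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("{"):
                obj = json.loads(line)
                docs.append(
                    DocumentRecord(doc_id=obj["doc_id"], sentences=tuple(obj["sentences"]))
                )
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise InputError(f"corpus {path} line {lineno}: expected doc_id TAB text")
            sentences = tuple(s for s in parts[1].split(sentence_delimiter) if s.strip())
            docs.append(DocumentRecord(doc_id=parts[0], sentences=sentences))
    return docs


def read_lexicon_tsv(path: str | Path) -> Lexicon:
    """Read a lexicon TSV: name, id, kind, organism (kind 'blocked' allowed)."""
    entries: dict[str, tuple[str, str, str]] = {}
    blocked: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, entity, kind, organism = line.rstrip("\n").split("\t")
            norm_name = _normalize_name(name)
            if kind == "blocked":
                blocked.add(norm_name)
            else:
                entries[norm_name] = (entity, kind, organism)
    return Lexicon(entries=entries, blocked=blocked)


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(lexicon.entries):
            entity, kind, organism = lexicon.entries[name]
            fh.write(f"{name}\t{entity}\t{kind}\t{organism}\n")
        for name in sorted(lexicon.blocked):
            fh.write(f"{name}\t-\tblocked\t-\n")


def write_scored_tsv(scored: Iterable[ScoredPair], path: str | Path) -> None:
    """Scored-pair table: protein, term, C, S, z, stars."""
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tterm\tcount\tscore\tz\tstars\n")
        for sp in sorted(scored, key=lambda s: (s.protein, s.compartment)):
            fh.write(
                f"{sp.protein}\t{sp.compartment}\t{sp.count:.6g}\t"
                f"{sp.score:.6g}\t{sp.z:.6g}\t{sp.stars:.6g}\n"
            )


def read_scored_tsv(path: str | Path) -> list[ScoredPair]:
    """Read back a scored-pair table written by :func:`write_scored_tsv`."""
    pairs: list[ScoredPair] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            protein, term, c, s, z, stars = line.rstrip("\n").split("\t")
            pairs.append(
                ScoredPair(
                    protein=protein,
                    compartment=term,
                    count=float(c),
                    score=float(s),
                    z=float(z),
                    stars=float(stars),
                )
            )
    return pairs


def write_matches_tsv(
    tagged_docs: Iterable[tuple[DocumentRecord, Sequence[Match]]], path: str | Path
) -> None:
    """Match report mirroring a highlighted-abstract view."""
    with open(path, "w", newline="\n") as fh:
        fh.write("doc_id\tsentence\tstart\tend\tentity\tkind\n")
        for doc, matches in tagged_docs:
            for m in matches:
                fh.write(
                    f"{doc.doc_id}\t{m.sentence}\t{m.start}\t{m.end}\t{m.entity}\t{m.kind}\n"
                )
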