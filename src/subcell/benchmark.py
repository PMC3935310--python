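"""Knowledge-derived gold standard and ROC evaluation of text mining.

Positives are (protein, compartment) pairs backed by five-star knowledge
evidence at slim level.  Negatives pair such a protein with every other slim
compartment for which *no* supplied evidence record exists at any confidence
level.  The evidence collection used for the negative predicate is supplied
by the caller and must exclude the channel under evaluation, otherwise every
scored pair would be disqualified and the ROC would be degenerate.

Benchmark pairs that were never scored can never be predicted positive, so
ROC curves truncate before reaching sensitivity 1 / FPR 1; the AUC is the
trapezoid area over the attained range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError
from .records import EvidenceRecord
from .textmining import ScoredPair

logger = logging.getLogger(__name__)

FIVE_STAR = 5.0


@dataclass
class BenchmarkSet:
    """Disjoint positive and negative (protein, slim term) pairs."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"benchmark pairs both positive and negative: {overlap}")


def build_benchmark(
    knowledge_slim: Iterable[EvidenceRecord],
    all_evidence_slim: Iterable[EvidenceRecord],
    slim_terms: Iterable[str],
) -> BenchmarkSet:
    """Construct the gold standard from slim-level evidence.

    *knowledge_slim* supplies the five-star anchors; *all_evidence_slim* is
    the union of records (any channel, any stars) that disqualify a
    (protein, term) pair from being a negative.
    """
    terms = list(slim_terms)
    positives: set[tuple[str, str]] = set()
    anchored: set[str] = set()
    for rec in knowledge_slim:
        if rec.stars >= FIVE_STAR:
            positives.add((rec.protein, rec.term))
            anchored.add(rec.protein)
    evidenced: set[tuple[str, str]] = {
        (rec.protein, rec.term) for rec in all_evidence_slim
    }
    evidenced |= positives
    negatives = {
        (protein, term)
        for protein in anchored
        for term in terms
        if (protein, term) not in evidenced
    }
    if not positives:
        logger.warning("no five-star knowledge evidence: benchmark is empty")
    return BenchmarkSet(positives=positives, negatives=negatives)


@dataclass
class RocCurve:
    """ROC points over the attained range, with trapezoid AUC."""

    points: list[tuple[float, float]]  # (FPR, sensitivity)
    auc: float
    max_fpr_reached: float
    max_sens_reached: float
    n_pos: int
    n_neg: int


def _curve(
    pairs_pos: set[tuple[str, str]],
    pairs_neg: set[tuple[str, str]],
    stars: Mapping[tuple[str, str], float],
) -> RocCurve:
    n_pos, n_neg = len(pairs_pos), len(pairs_neg)
    scored: list[tuple[float, bool]] = []
    for pair in pairs_pos:
        if pair in stars:
            scored.append((stars[pair], True))
    for pair in pairs_neg:
        if pair in stars:
            scored.append((stars[pair], False))
    scored.sort(key=lambda t: -t[0])
    n_pos_scored = sum(1 for _, is_pos in scored if is_pos)
    n_neg_scored = len(scored) - n_pos_scored

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(scored):
        j = i
        while j < len(scored) and scored[j][0] == scored[i][0]:
            if scored[j][1]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j

    # The AUC measures ranking quality over the attained range, i.e. among
    # the scored pairs; the truncation itself is reported via the max FPR and
    # sensitivity reached.  When everything is scored this is the ordinary
    # full-range trapezoid AUC.
    auc = 0.0
    if n_pos_scored and n_neg_scored:
        tp = fp = 0
        x_prev = y_prev = 0.0
        i = 0
        while i < len(scored):
            j = i
            while j < len(scored) and scored[j][0] == scored[i][0]:
                if scored[j][1]:
                    tp += 1
                else:
                    fp += 1
                j += 1
            x, y = fp / n_neg_scored, tp / n_pos_scored
            auc += (x - x_prev) * (y_prev + y) / 2.0
            x_prev, y_prev = x, y
            i = j
    return RocCurve(
        points=points,
        auc=auc,
        max_fpr_reached=points[-1][0],
        max_sens_reached=points[-1][1],
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc(
    benchmark: BenchmarkSet,
    scored: Iterable[ScoredPair],
) -> dict[str, RocCurve]:
    """ROC per slim compartment plus a pooled curve under key ``"pooled"``.

    Pairs are ranked by descending stars; ties are processed as one block so
    within-tie ordering has no effect.  Compartments without both positives
    and negatives are skipped with a warning.
    """
    stars = {(sp.protein, sp.compartment): sp.stars for sp in scored}
    curves: dict[str, RocCurve] = {}
    terms = {t for _, t in benchmark.positives} | {t for _, t in benchmark.negatives}
    for term in sorted(terms):
        pos = {pr for pr in benchmark.positives if pr[1] == term}
        neg = {pr for pr in benchmark.negatives if pr[1] == term}
        if not pos or not neg:
            logger.warning("compartment %s lacks positives or negatives: ROC skipped", term)
            continue
        curves[term] = _curve(pos, neg, stars)
    if benchmark.positives and benchmark.negatives:
        curves["pooled"] = _curve(benchmark.positives, benchmark.negatives, stars)
    return curves


def project_scored(
    scored: Iterable[ScoredPair], graph, slim
) -> list[ScoredPair]:
    """Project scored pairs onto slim compartments, keeping the strongest.

    Text-mining hits on fine-grained terms are lifted to their slim ancestors
    before ROC evaluation, matching the slim-level benchmark definition.
    Pairs whose term has no slim ancestor are dropped.
    """
    slim_terms = set(slim.slim_terms)
    best: dict[tuple[str, str], ScoredPair] = {}
    for sp in scored:
        if sp.compartment not in graph:
            continue
        for term in graph.ancestors(sp.compartment) & slim_terms:
            key = (sp.protein, term)
            cur = best.get(key)
            if cur is None or sp.stars > cur.stars:
                best[key] = ScoredPair(
                    protein=sp.protein,
                    compartment=term,
                    count=sp.count,
                    score=sp.score,
                    z=sp.z,
                    stars=sp.stars,
                )
    return sorted(best.values(), key=lambda s: (s.protein, s.compartment))


def write_benchmark_tsv(benchmark: BenchmarkSet, path: str | Path) -> None:
    """Benchmark table: protein, term, label in {pos, neg}."""
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tterm\tlabel\n")
        for protein, term in sorted(benchmark.positives):
            fh.write(f"{protein}\t{term}\tpos\n")
        for protein, term in sorted(benchmark.negatives):
            fh.write(f"{protein}\t{term}\tneg\n")


def read_benchmark_tsv(path: str | Path) -> BenchmarkSet:
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein"):
            raise InputError(f"{path}: missing benchmark header")
        for line in fh:
            protein, term, label = line.rstrip("\n").split("\t")
            (positives if label == "pos" else negatives).add((protein, term))
    return BenchmarkSet(positives=positives, negatives=negatives)


def write_roc_tsv(curves: Mapping[str, RocCurve], path: str | Path) -> None:
    """ROC points per compartment: term, fpr, sensitivity (plus AUC rows)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("term\tfpr\tsensitivity\tauc\n")
        for term in sorted(curves):
            curve = curves[term]
            for fpr, sens in curve.points:
                fh.write(f"{term}\t{fpr:.6g}\t{sens:.6g}\t{curve.auc:.6g}\n")
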