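"""End-to-end orchestration: from raw inputs to the unified table, the
text-mining benchmark and the compartment co-localization network.

The negative-example predicate of the benchmark is evaluated against the
knowledge, experiments and predictions channels only — the text-mining
channel under evaluation is deliberately excluded so scored pairs can appear
among the negatives (otherwise the ROC would have no false positives by
construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import benchmark as bm
from . import network as net
from .channels import knowledge_records, score_hpa
from .ontology import backtrack
from .predictions import psort_stars, yloc_stars
from .records import CuratedAnnotation, DocumentRecord, EvidenceRecord, HpaRecord, PredictionRecord
from .synthetic import SyntheticWorld, build_world_lexicon
from .textmining import (
    Match,
    ScoredPair,
    ScoringParams,
    compile_matcher,
    count_pairs,
    score_all,
    textmining_records,
)
from .unify import UnifiedTable, map_aliases, unify

logger = logging.getLogger(__name__)


def hpa_records(records: list[HpaRecord], location_map: dict[str, str]) -> list[EvidenceRecord]:
    """Score in-memory antibody-screen records into the experiments channel."""
    out: list[EvidenceRecord] = []
    for rec in records:
        term = location_map.get(rec.location_label)
        if term is None:
            continue
        stars = score_hpa(rec)
        if stars is None:
            continue
        out.append(
            EvidenceRecord(
                protein=rec.protein,
                term=term,
                channel="experiments",
                source="HPA",
                stars=float(stars),
                provenance=f"{rec.mode}:{rec.level}",
            )
        )
    return out


def prediction_records(
    psort_rows: list[tuple[str, str, int, int]],
    yloc_rows: list[tuple[str, str, float]],
    label_map: dict[str, str],
) -> list[EvidenceRecord]:
    """Calibrate raw predictor rows and convert them to evidence records."""
    records: list[EvidenceRecord] = []
    for protein, label, v, k in psort_rows:
        term = label_map.get(label)
        if term is None:
            continue
        stars = psort_stars(v, k)
        if stars <= 0:
            continue
        records.append(
            PredictionRecord(
                protein=protein, term=term, tool="psort", raw=float(v), stars=stars
            ).to_evidence()
        )
    for protein, label, p in yloc_rows:
        term = label_map.get(label)
        if term is None:
            continue
        stars = yloc_stars(p)
        if stars is None:
            continue
        records.append(
            PredictionRecord(
                protein=protein, term=term, tool="yloc", raw=p, stars=stars
            ).to_evidence()
        )
    return records


def tag_corpus(
    docs: list[DocumentRecord], lexicon
) -> list[tuple[DocumentRecord, list[Match]]]:
    matcher = compile_matcher(lexicon)
    return [(doc, [m for i, s in enumerate(doc.sentences) for m in matcher.scan(i, s)]) for doc in docs]


@dataclass
class PipelineResult:
    """Everything the downstream analyses need, in one place."""

    channels: dict[str, list[EvidenceRecord]]
    table: UnifiedTable
    scored_raw: list[ScoredPair]
    scored_slim: list[ScoredPair]
    benchmark: bm.BenchmarkSet
    curves: dict[str, bm.RocCurve]
    links: net.LinkSet
    network: list[net.CompartmentLink]


def run_world(
    world: SyntheticWorld,
    docs: list[DocumentRecord],
    annotations: list[CuratedAnnotation],
    hpa: list[HpaRecord],
    psort_rows: list[tuple[str, str, int, int]],
    yloc_rows: list[tuple[str, str, float]],
    params: ScoringParams = ScoringParams(),
    n_perm: int = net.DEFAULT_N_PERM,
    perm_seed: int = 0,
    fdr_q: float = net.DEFAULT_FDR,
    min_stars: float = net.DEFAULT_MIN_STARS,
) -> PipelineResult:
    """Run every stage on in-memory synthetic inputs."""
    graph, slim = world.ontology, world.slim
    location_map = dict(world.label_to_term)

    knowledge_raw = knowledge_records(annotations)
    knowledge, _ = map_aliases(knowledge_raw, world.alias_table, taxon="9606")
    experiments = hpa_records(hpa, location_map)
    predictions = prediction_records(psort_rows, yloc_rows, location_map)

    lexicon = build_world_lexicon(world)
    tagged = tag_corpus(docs, lexicon)
    counts = count_pairs(tagged, params, organism="9606")
    counts.validate()
    scored = score_all(counts, params)
    textmining = textmining_records(scored)

    channels = {
        "knowledge": knowledge,
        "experiments": experiments,
        "textmining": textmining,
        "predictions": predictions,
    }
    table = unify(channels, graph, slim)

    knowledge_slim = list(backtrack(knowledge, graph, slim))
    exclusion_slim = knowledge_slim + list(
        backtrack(experiments + predictions, graph, slim)
    )
    bench = bm.build_benchmark(knowledge_slim, exclusion_slim, slim.slim_terms)
    scored_slim = bm.project_scored(scored, graph, slim)
    curves = bm.roc(bench, scored_slim)

    links = net.filter_links(table, min_stars_exclusive=min_stars)
    network = net.coloc_network(links, n_perm=n_perm, seed=perm_seed, q=fdr_q)

    return PipelineResult(
        channels=channels,
        table=table,
        scored_raw=scored,
        scored_slim=scored_slim,
        benchmark=bench,
        curves=curves,
        links=links,
        network=network,
    )
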