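"""Self-contained synthetic fixtures with planted localization signal.

The generator builds a toy cellular-component ontology (slim compartments
plus fine-grained children), a proteome with known compartment membership,
and every input the pipeline consumes: an abstract corpus whose co-mention
statistics reflect the planted truth, curated GAF-style annotations,
antibody-screen records, predictor outputs, an alias table and a tagging
lexicon.  Everything is deterministic under a fixed seed.

The planted world emulates the statistical structure the analysis assumes:
proteins are often multi-localized, a handful of compartment pairs share
proteins well above independence (mirroring the trafficking-pathway
co-localization structure seen in real cells), and a small fraction of
proteins is co-mentioned with a compartment they do not inhabit (functional
confounding — the known nucleus/plasma-membrane failure mode of co-mention
text mining).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .ontology import SLIM_LABELS, OntologyGraph, SlimSet, load_obo
from .records import CuratedAnnotation, DocumentRecord, HpaRecord
from .channels import EVIDENCE_CODE_STARS
from .textmining import Lexicon, build_lexicon, write_lexicon_tsv
from .unify import AliasTable

logger = logging.getLogger(__name__)

TAXON = "9606"

#: Planted co-localized compartment pairs (label_a, label_b, excess rate):
#: a protein truly in A additionally acquires B with the given probability.
#: The topology follows the classic trafficking pathways (nucleocytosolic
#: shuttling, secretory route, endocytic route, peroxisome biogenesis).
DEFAULT_CO_LOC_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("cytosol", "nucleus", 0.35),
    ("cytosol", "cytoskeleton", 0.25),
    ("nucleus", "cytoskeleton", 0.20),
    ("endoplasmic reticulum", "Golgi apparatus", 0.30),
    ("Golgi apparatus", "plasma membrane", 0.20),
    ("endoplasmic reticulum", "peroxisome", 0.20),
    ("plasma membrane", "endosome", 0.25),
    ("endosome", "lysosome", 0.25),
)

#: Names planted to exercise dictionary hygiene.
CONFLICTING_ALIAS = "nucleus"  # collides with a compartment label
AMBIGUOUS_ALIAS = "AMBIG1"  # maps to two canonical ids
PROMISCUOUS_ALIAS = "CAG"  # frequent acronym, blocked by match count

_CHILD_SUFFIXES = ("lumen", "membrane region", "matrix")


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic proteome."""

    n_proteins: int = 2000
    slim_schema: str = "animal"
    multi_loc_rate: float = 0.3
    co_loc_pairs: tuple[tuple[str, str, float], ...] = DEFAULT_CO_LOC_PAIRS
    confounder_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.multi_loc_rate, self.confounder_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"rate {rate} outside [0, 1]")
        labels = set(SLIM_LABELS[self.slim_schema])
        for a, b, excess in self.co_loc_pairs:
            if not (0.0 <= excess <= 1.0):
                raise ValidationError(f"co-localization excess {excess} outside [0, 1]")
            if a not in labels or b not in labels:
                raise ValidationError(f"co-localization pair ({a}, {b}) not in slim")
        if self.n_proteins < 1:
            raise ValidationError("need at least one protein")


@dataclass
class SyntheticWorld:
    """A generated proteome with its toy ontology and ground truth."""

    config: WorldConfig
    ontology: OntologyGraph
    slim: SlimSet
    truth: dict[str, set[str]]  # canonical protein id -> slim term ids
    protein_ids: list[str]
    gene_names: dict[str, str]  # canonical id -> gene symbol
    label_to_term: dict[str, str]  # compartment label -> slim term id
    child_terms: dict[str, list[str]]  # slim term -> fine-grained children
    alias_rows: list[tuple[str, str, str, str]]
    protein_names: dict[str, str]  # taggable name -> canonical id
    match_counts: dict[str, int]  # corpus-frequency table for blocking
    confounders: dict[str, str]  # protein -> confounded slim term

    @property
    def alias_table(self) -> AliasTable:
        return AliasTable(rows=list(self.alias_rows))

    def co_membership_rate(self, label_a: str, label_b: str) -> float:
        ta, tb = self.label_to_term[label_a], self.label_to_term[label_b]
        both = sum(1 for terms in self.truth.values() if ta in terms and tb in terms)
        return both / len(self.truth)


def _build_toy_ontology(schema: str) -> tuple[OntologyGraph, SlimSet, dict[str, str], dict[str, list[str]]]:
    labels = SLIM_LABELS[schema]
    terms: set[str] = {"TOY:0000"}
    names: dict[str, str] = {"TOY:0000": "cell"}
    edges: set[tuple[str, str, str]] = set()
    label_to_term: dict[str, str] = {}
    child_terms: dict[str, list[str]] = {}
    for i, label in enumerate(labels):
        slim_id = f"TOY:{100 + i:04d}"
        terms.add(slim_id)
        names[slim_id] = label
        edges.add((slim_id, "TOY:0000", "is_a"))
        label_to_term[label] = slim_id
        children = []
        for j, suffix in enumerate(_CHILD_SUFFIXES):
            child_id = f"TOY:{1000 + 10 * i + j:04d}"
            terms.add(child_id)
            names[child_id] = f"{label} {suffix}"
            relation = "part_of" if j == 1 else "is_a"
            parent = slim_id if j < 2 else children[0]  # third child is a grandchild
            edges.add((child_id, parent, relation))
            children.append(child_id)
        child_terms[slim_id] = children
    # a cellular component outside every slim compartment: projection drops it
    terms.add("TOY:9000")
    names["TOY:9000"] = "cell periphery"
    edges.add(("TOY:9000", "TOY:0000", "is_a"))
    graph = OntologyGraph(terms=terms, names=names, edges=edges)
    slim = SlimSet(schema=schema, slim_terms=tuple(label_to_term[l] for l in labels))
    return graph, slim, label_to_term, child_terms


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a proteome with planted localization and co-localization."""
    rng = np.random.default_rng(config.seed)
    graph, slim, label_to_term, child_terms = _build_toy_ontology(config.slim_schema)
    slim_terms = list(slim.slim_terms)

    protein_ids = [f"ENSP{i:05d}" for i in range(config.n_proteins)]
    truth: dict[str, set[str]] = {}
    for pid in protein_ids:
        compartments = {slim_terms[rng.integers(len(slim_terms))]}
        if rng.random() < config.multi_loc_rate:
            extra = slim_terms[rng.integers(len(slim_terms))]
            compartments.add(extra)
        truth[pid] = compartments
    for label_a, label_b, excess in config.co_loc_pairs:
        ta, tb = label_to_term[label_a], label_to_term[label_b]
        for pid in protein_ids:
            if ta in truth[pid] and tb not in truth[pid] and rng.random() < excess:
                truth[pid].add(tb)

    gene_names = {pid: f"GN{i}" for i, pid in enumerate(protein_ids)}
    alias_rows: list[tuple[str, str, str, str]] = []
    protein_names: dict[str, str] = {}
    for i, pid in enumerate(protein_ids):
        accession = f"UP{i:05d}"
        alias_rows.append((TAXON, pid, accession, "UniProt_AC"))
        alias_rows.append((TAXON, pid, gene_names[pid], "gene_symbol"))
        protein_names[gene_names[pid]] = pid
        protein_names[pid] = pid
    # planted hygiene cases
    if config.n_proteins >= 4:
        protein_names[CONFLICTING_ALIAS] = protein_ids[0]
        alias_rows.append((TAXON, protein_ids[1], AMBIGUOUS_ALIAS, "gene_symbol"))
        alias_rows.append((TAXON, protein_ids[2], AMBIGUOUS_ALIAS, "gene_symbol"))
        protein_names[PROMISCUOUS_ALIAS] = protein_ids[3]
    match_counts = {name: 3 for name in protein_names}
    match_counts[PROMISCUOUS_ALIAS] = 5000

    n_confounded = int(round(config.confounder_rate * config.n_proteins))
    confounders: dict[str, str] = {}
    confounder_targets = [label_to_term[l] for l in ("nucleus", "plasma membrane")]
    if n_confounded:
        chosen = rng.choice(config.n_proteins, size=n_confounded, replace=False)
        for idx in sorted(chosen):
            pid = protein_ids[idx]
            options = [t for t in confounder_targets if t not in truth[pid]]
            if options:
                confounders[pid] = options[int(rng.integers(len(options)))]

    return SyntheticWorld(
        config=config,
        ontology=graph,
        slim=slim,
        truth=truth,
        protein_ids=protein_ids,
        gene_names=gene_names,
        label_to_term=label_to_term,
        child_terms=child_terms,
        alias_rows=alias_rows,
        protein_names=protein_names,
        match_counts=match_counts,
        confounders=confounders,
    )


# ---------------------------------------------------------------------------
# Corpus


def generate_corpus(
    world: SyntheticWorld,
    n_abstracts: int | None = None,
    same_sentence_rate: float = 0.5,
    noise_rate: float = 0.10,
    seed: int = 0,
) -> list[DocumentRecord]:
    """Draw abstracts whose co-mention statistics follow the planted truth.

    Each abstract features one protein; with probability ``1 - noise_rate``
    it is co-mentioned with one of its true compartments, otherwise with a
    random false one.  Confounded proteins are additionally co-mentioned with
    their confounder compartment, planting functional association without
    localization.  The compartment is named by its slim label most of the
    time and by a fine-grained child label otherwise, so projection is
    exercised end to end.
    """
    for rate in (same_sentence_rate, noise_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"rate {rate} outside [0, 1]")
    if n_abstracts is None:
        n_abstracts = 20 * len(world.protein_ids)
    rng = np.random.default_rng(seed)
    term_names = world.ontology.names
    slim_terms = list(world.slim.slim_terms)
    docs: list[DocumentRecord] = []
    for k in range(n_abstracts):
        pid = world.protein_ids[int(rng.integers(len(world.protein_ids)))]
        gene = world.gene_names[pid]
        sentences: list[str] = []
        kind = rng.random()
        if kind < 0.05:  # protein-only abstract: marginal mass, no pair
            other = world.gene_names[
                world.protein_ids[int(rng.integers(len(world.protein_ids)))]
            ]
            sentences = [
                f"{gene} was purified and characterized.",
                f"{other} served as a control.",
            ]
        elif kind < 0.10:  # compartment-only abstract
            term = slim_terms[int(rng.integers(len(slim_terms)))]
            sentences = [f"The {term_names[term]} was isolated by fractionation."]
        else:
            true_terms = sorted(world.truth[pid])
            if pid in world.confounders and rng.random() < 0.5:
                term = world.confounders[pid]
            elif noise_rate > 0 and rng.random() < noise_rate:
                false_terms = [t for t in slim_terms if t not in world.truth[pid]]
                term = (
                    false_terms[int(rng.integers(len(false_terms)))]
                    if false_terms
                    else true_terms[0]
                )
            else:
                term = true_terms[int(rng.integers(len(true_terms)))]
            if rng.random() < 0.2:  # sometimes cite a fine-grained subcompartment
                children = world.child_terms.get(term)
                if children:
                    term = children[int(rng.integers(len(children)))]
            comp = term_names[term]
            if rng.random() < same_sentence_rate:
                sentences.append(f"{gene} localizes to the {comp}.")
            else:
                sentences.append(f"{gene} was characterized in this study.")
                sentences.append(f"Immunostaining revealed strong enrichment in the {comp}.")
        if rng.random() < 0.3:
            sentences.append("These results extend previous observations.")
        order = rng.permutation(len(sentences)) if len(sentences) > 1 else [0]
        docs.append(
            DocumentRecord(
                doc_id=f"SYN{k:07d}",
                sentences=tuple(sentences[i] for i in order),
            )
        )
    return docs


# ---------------------------------------------------------------------------
# Curated annotations and antibody screens

_FOUR_STAR_CODES = ("IDA", "TAS", "NAS", "CURATED")
_LOWER_CODES = tuple(c for c, s in EVIDENCE_CODE_STARS.items() if s < 4)
_TRUSTED = ("UniProtKB", "MGI", "SGD")


def generate_annotations(
    world: SyntheticWorld,
    coverage: float = 0.75,
    five_star_rate: float = 0.5,
    hpa_rate: float = 0.3,
    seed: int = 0,
) -> tuple[list[CuratedAnnotation], list[HpaRecord]]:
    """Draw curated annotations and antibody-screen records from the truth.

    Each true (protein, compartment) pair is annotated with probability
    *coverage*, at a fine-grained child term two thirds of the time.  A
    *five_star_rate* fraction receives a four-star evidence code from a
    trusted source (five stars after upgrade); the rest draw weaker codes and
    mixed sources.  Annotations are keyed by the UniProt-style accession so
    identifier unification is exercised.
    """
    for rate in (coverage, five_star_rate, hpa_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    term_names = world.ontology.names
    annotations: list[CuratedAnnotation] = []
    hpa: list[HpaRecord] = []
    for i, pid in enumerate(world.protein_ids):
        accession = f"UP{i:05d}"
        for term in sorted(world.truth[pid]):
            if rng.random() >= coverage:
                continue
            target = term
            if rng.random() < 2 / 3:
                children = world.child_terms[term]
                target = children[int(rng.integers(len(children)))]
            if rng.random() < five_star_rate:
                code = _FOUR_STAR_CODES[int(rng.integers(len(_FOUR_STAR_CODES)))]
                source = _TRUSTED[int(rng.integers(len(_TRUSTED)))]
            else:
                code = _LOWER_CODES[int(rng.integers(len(_LOWER_CODES)))]
                source = (
                    _TRUSTED[int(rng.integers(len(_TRUSTED)))]
                    if rng.random() < 0.5
                    else "other"
                )
            annotations.append(
                CuratedAnnotation(
                    protein=accession, term=target, source=source, evidence_code=code
                )
            )
        if rng.random() < hpa_rate:
            term = sorted(world.truth[pid])[0]
            label = term_names[term]
            if rng.random() < 0.6:
                level = str(
                    rng.choice(
                        ["high", "medium", "low", "very low"],
                        p=[0.3, 0.4, 0.2, 0.1],
                    )
                )
                hpa.append(
                    HpaRecord(
                        protein=pid,
                        location_label=label,
                        mode="reliability",
                        level=level,
                        antibody_count=int(rng.integers(2, 5)),
                    )
                )
            else:
                level = str(
                    rng.choice(
                        ["supportive", "uncertain", "non-supportive"],
                        p=[0.6, 0.25, 0.15],
                    )
                )
                hpa.append(
                    HpaRecord(
                        protein=pid,
                        location_label=label,
                        mode="validation",
                        level=level,
                        antibody_count=1,
                    )
                )
    return annotations, hpa


# ---------------------------------------------------------------------------
# Predictions


def generate_predictions(
    world: SyntheticWorld,
    accuracy: float = 0.8,
    k: int = 32,
    seed: int = 0,
) -> tuple[list[tuple[str, str, int, int]], list[tuple[str, str, float]]]:
    """Draw raw predictor outputs concentrated on the true compartments.

    Returns ``(psort_rows, yloc_rows)``: k-NN rows (protein, label, v, k) and
    posterior rows (protein, label, p).  With probability *accuracy* the
    top-scoring compartment is a true one, otherwise a random decoy.
    Posteriors pile up near 0 and 1 by construction.
    """
    if not (0.0 <= accuracy <= 1.0):
        raise ValidationError("accuracy outside [0, 1]")
    rng = np.random.default_rng(seed)
    term_names = world.ontology.names
    slim_terms = list(world.slim.slim_terms)
    psort_rows: list[tuple[str, str, int, int]] = []
    yloc_rows: list[tuple[str, str, float]] = []
    for pid in world.protein_ids:
        true_terms = sorted(world.truth[pid])
        if rng.random() < accuracy:
            top = true_terms[int(rng.integers(len(true_terms)))]
        else:
            top = slim_terms[int(rng.integers(len(slim_terms)))]
        top_v = int(rng.integers(22, k + 1))
        psort_rows.append((pid, term_names[top], top_v, k))
        scatter = slim_terms[int(rng.integers(len(slim_terms)))]
        if scatter != top:
            psort_rows.append((pid, term_names[scatter], int(rng.integers(1, 6)), k))

        if rng.random() < accuracy:
            yloc_top = true_terms[int(rng.integers(len(true_terms)))]
        else:
            yloc_top = slim_terms[int(rng.integers(len(slim_terms)))]
        for term in slim_terms:
            if term == yloc_top:
                p = float(1.0 - 10 ** -rng.uniform(1.5, 4.0))
            else:
                p = float(10 ** -rng.uniform(1.5, 4.0))
                if rng.random() < 0.05:
                    p = float(rng.uniform(0.1, 0.4))
            yloc_rows.append((pid, term_names[term], round(p, 6)))
    return psort_rows, yloc_rows


# ---------------------------------------------------------------------------
# File writers (every format the other modules read)


def write_obo(world: SyntheticWorld, path: str | Path) -> None:
    """Write the toy ontology, including decoy stanzas the loader must skip."""
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in sorted(world.ontology.edges):
        parents.setdefault(child, []).append((parent, relation))
    with open(path, "w", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for term in sorted(world.ontology.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {world.ontology.names[term]}\n")
            fh.write("namespace: cellular_component\n")
            for parent, relation in parents.get(term, []):
                if relation == "is_a":
                    fh.write(f"is_a: {parent} ! {world.ontology.names[parent]}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
        # decoys: wrong namespace, an obsolete term, a non-traversal relation
        fh.write(
            "\n[Term]\nid: TOY:9001\nname: toy process\n"
            "namespace: biological_process\n"
        )
        fh.write(
            "\n[Term]\nid: TOY:9002\nname: retired compartment\n"
            "namespace: cellular_component\nis_obsolete: true\n"
        )
        fh.write(
            "\n[Term]\nid: TOY:9003\nname: regulator region\n"
            "namespace: cellular_component\n"
            "relationship: regulates TOY:0000\n"
            "is_a: TOY:0000 ! cell\n"
        )


def write_slim_yaml(world: SyntheticWorld, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(
            {world.slim.schema: list(world.slim.slim_terms)}, fh, sort_keys=True
        )


def write_gaf(annotations: Sequence[CuratedAnnotation], path: str | Path) -> None:
    """GAF 2.2 file; assigned_by carries the source database."""
    with open(path, "w", newline="\n") as fh:
        fh.write("!gaf-version: 2.2\n")
        for a in annotations:
            fields = [
                "TOYDB", a.protein, a.protein, "", a.term, "SYN:0000001",
                a.evidence_code, "", "C", "", "", "protein",
                f"taxon:{TAXON}", "20260101", a.source, "", "",
            ]
            fh.write("\t".join(fields) + "\n")


def write_hpa_tsv(records: Sequence[HpaRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene\tlocation\tmode\tlevel\tn_antibodies\n")
        for r in records:
            fh.write(
                f"{r.protein}\t{r.location_label}\t{r.mode}\t{r.level}\t{r.antibody_count}\n"
            )


def write_location_map(world: SyntheticWorld, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for label in sorted(world.label_to_term):
            fh.write(f"{label}\t{world.label_to_term[label]}\n")


def write_corpus_tsv(
    docs: Sequence[DocumentRecord], path: str | Path, sentence_delimiter: str = "|"
) -> None:
    with open(path, "w", newline="\n") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}\t{sentence_delimiter.join(doc.sentences)}\n")


def write_alias_tsv(world: SyntheticWorld, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for taxon, canonical, alias, source in world.alias_rows:
            fh.write(f"{taxon}\t{canonical}\t{alias}\t{source}\n")


def write_psort_tsv(rows: Sequence[tuple[str, str, int, int]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tlocation\tscore\tk\n")
        for protein, label, v, k in rows:
            fh.write(f"{protein}\t{label}\t{v}\t{k}\n")


def write_yloc_tsv(rows: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tlocation\tscore\n")
        for protein, label, p in rows:
            fh.write(f"{protein}\t{label}\t{p:.6g}\n")


def build_world_lexicon(world: SyntheticWorld, block_threshold: int = 2000) -> Lexicon:
    return build_lexicon(
        protein_names=world.protein_names,
        ontology=world.ontology,
        match_counts=world.match_counts,
        block_threshold=block_threshold,
        organism=TAXON,
    )


def synth_all(
    config: WorldConfig,
    outdir: str | Path,
    n_abstracts: int | None = None,
    same_sentence_rate: float = 0.5,
    noise_rate: float = 0.10,
    coverage: float = 0.75,
    five_star_rate: float = 0.5,
    prediction_accuracy: float = 0.8,
) -> dict[str, Path]:
    """Generate the complete fixture directory; returns a path manifest.

    Sub-generators draw their own streams from seeds derived from the world
    seed, so regenerating with the same configuration is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = generate_world(config)
    docs = generate_corpus(
        world,
        n_abstracts=n_abstracts,
        same_sentence_rate=same_sentence_rate,
        noise_rate=noise_rate,
        seed=config.seed + 1,
    )
    annotations, hpa = generate_annotations(
        world, coverage=coverage, five_star_rate=five_star_rate, seed=config.seed + 2
    )
    psort_rows, yloc_rows = generate_predictions(
        world, accuracy=prediction_accuracy, seed=config.seed + 3
    )
    manifest = {
        "obo": outdir / "ontology.obo",
        "slim": outdir / "slim.yaml",
        "gaf": outdir / "knowledge.gaf",
        "hpa": outdir / "hpa.tsv",
        "location_map": outdir / "locations.tsv",
        "corpus": outdir / "corpus.tsv",
        "lexicon": outdir / "lexicon.tsv",
        "aliases": outdir / "aliases.tsv",
        "psort": outdir / "psort.tsv",
        "yloc": outdir / "yloc.tsv",
    }
    write_obo(world, manifest["obo"])
    write_slim_yaml(world, manifest["slim"])
    write_gaf(annotations, manifest["gaf"])
    write_hpa_tsv(hpa, manifest["hpa"])
    write_location_map(world, manifest["location_map"])
    write_corpus_tsv(docs, manifest["corpus"])
    write_lexicon_tsv(build_world_lexicon(world), manifest["lexicon"])
    write_alias_tsv(world, manifest["aliases"])
    write_psort_tsv(psort_rows, manifest["psort"])
    write_yloc_tsv(yloc_rows, manifest["yloc"])
    logger.info("synthetic fixture written to %s", outdir)
    return manifest


def load_world_ontology(obo_path: str | Path) -> OntologyGraph:
    """Round-trip helper: read back the generated OBO file."""
    return load_obo(obo_path)
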