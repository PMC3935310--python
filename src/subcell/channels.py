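"""Knowledge and experiments channels: curated annotations and antibody screens.

Curated annotations are scored from their evidence code — four stars for
direct, author- or curator-backed codes, down to one star for weak inferences
— with a one-star upgrade for annotations from the trusted curated databases
(UniProtKB and the model-organism databases), capping the knowledge channel
at five stars.  Antibody-screen records carry either a multi-antibody
*reliability* level (four stars down to one) or a single-antibody
*validation* level (supportive = 3, uncertain = 1, non-supportive dropped).
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError
from .records import CuratedAnnotation, EvidenceRecord, HpaRecord

logger = logging.getLogger(__name__)

#: Base stars per evidence code (GO codes plus UniProtKB-style qualifiers).
EVIDENCE_CODE_STARS: dict[str, int] = {
    **{c: 4 for c in ("CURATED", "IDA", "TAS", "NAS")},
    **{
        c: 3
        for c in (
            "PROBABLE", "EXP", "IPI", "IMP", "IGI", "IEP", "ISS", "ISO",
            "ISA", "ISM", "IBA", "IBD", "IKR", "IMR", "IRD", "IC",
        )
    },
    **{c: 2 for c in ("POTENTIAL", "IGC", "IEA")},
    **{c: 1 for c in ("BY SIMILARITY", "RCA", "NR")},
}

#: Sources whose annotations are upgraded by one star.
TRUSTED_SOURCES = frozenset({"UniProtKB", "MGI", "SGD", "FlyBase", "WormBase"})

#: Map assigned_by tokens onto the source vocabulary.
DEFAULT_SOURCE_VOCABULARY: dict[str, str] = {
    "uniprotkb": "UniProtKB",
    "uniprot": "UniProtKB",
    "mgi": "MGI",
    "sgd": "SGD",
    "flybase": "FlyBase",
    "wormbase": "WormBase",
    "wb": "WormBase",
}

RELIABILITY_STARS = {"high": 4, "medium": 3, "low": 2, "very low": 1}
VALIDATION_STARS = {"supportive": 3, "uncertain": 1}  # non-supportive dropped


def normalize_code(code: str) -> str:
    """Trim, upper-case and collapse internal whitespace of an evidence code."""
    return re.sub(r"\s+", " ", code.strip()).upper()


def score_evidence_code(
    code: str,
    source: str,
    trusted_sources: frozenset[str] | set[str] = TRUSTED_SOURCES,
) -> int:
    """Stars for a curated annotation: base from the code, +1 for trusted sources.

    Unknown codes score a conservative single star (with a warning); the
    result is capped at five.
    """
    norm = normalize_code(code)
    base = EVIDENCE_CODE_STARS.get(norm)
    if base is None:
        logger.warning("unknown evidence code %r: scored 1 star", code)
        base = 1
    if source in trusted_sources:
        base += 1
    return min(base, 5)


def score_hpa(record: HpaRecord) -> int | None:
    """Stars for an antibody-screen record; ``None`` means "do not import"."""
    level = record.level.strip().lower()
    if record.mode == "reliability":
        return RELIABILITY_STARS[level]
    if level == "non-supportive":
        return None
    return VALIDATION_STARS[level]


def map_source(assigned_by: str, vocabulary: Mapping[str, str] | None = None) -> str:
    vocab = DEFAULT_SOURCE_VOCABULARY if vocabulary is None else vocabulary
    return vocab.get(assigned_by.strip().lower(), "other")


def import_gaf(
    path: str | Path, source_vocabulary: Mapping[str, str] | None = None
) -> list[CuratedAnnotation]:
    """Read cellular-component rows (aspect C) from a GAF 2.x file.

    Columns used: DB Object ID (2), GO ID (5), Evidence Code (7), Aspect (9)
    and Assigned By (15).  Comment lines start with ``!``; malformed rows are
    skipped with a line-number warning.
    """
    annotations: list[CuratedAnnotation] = []
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot read GAF file {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                logger.warning("GAF %s line %d: %d columns, skipped", path, lineno, len(fields))
                continue
            if fields[8] != "C":
                continue
            protein, term, code = fields[1], fields[4], fields[6]
            if not protein or not term or not code:
                logger.warning("GAF %s line %d: empty key field, skipped", path, lineno)
                continue
            annotations.append(
                CuratedAnnotation(
                    protein=protein,
                    term=term,
                    source=map_source(fields[14], source_vocabulary),
                    evidence_code=code,
                )
            )
    return annotations


def knowledge_records(
    annotations: Iterable[CuratedAnnotation],
    trusted_sources: frozenset[str] | set[str] = TRUSTED_SOURCES,
) -> list[EvidenceRecord]:
    """Score curated annotations into knowledge-channel evidence records."""
    return [
        EvidenceRecord(
            protein=a.protein,
            term=a.term,
            channel="knowledge",
            source=a.source,
            stars=float(score_evidence_code(a.evidence_code, a.source, trusted_sources)),
            provenance=normalize_code(a.evidence_code),
        )
        for a in annotations
    ]


def read_location_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping free-text location labels to term ids."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2 and row[0] and not row[0].startswith("#"):
                mapping[row[0]] = row[1]
    if not mapping:
        raise InputError(f"location map {path} is empty")
    return mapping


def import_hpa_tsv(
    path: str | Path, location_map: Mapping[str, str]
) -> tuple[list[EvidenceRecord], int]:
    """Read antibody-screen records into experiments-channel evidence.

    Expected columns: gene, location, mode, level, n_antibodies.  Returns the
    records plus the number of rows skipped (unmapped label, bad row, or a
    non-supportive validation level).
    """
    records: list[EvidenceRecord] = []
    skipped = 0
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot read HPA file {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            try:
                rec = HpaRecord(
                    protein=row["gene"],
                    location_label=row["location"],
                    mode=row["mode"],
                    level=row["level"],
                    antibody_count=int(row.get("n_antibodies") or 1),
                )
            except Exception as exc:
                logger.warning("HPA row %r rejected: %s", row, exc)
                skipped += 1
                continue
            term = location_map.get(rec.location_label)
            if term is None:
                logger.warning("unmapped HPA location %r: skipped", rec.location_label)
                skipped += 1
                continue
            stars = score_hpa(rec)
            if stars is None:
                skipped += 1
                continue
            records.append(
                EvidenceRecord(
                    protein=rec.protein,
                    term=term,
                    channel="experiments",
                    source="HPA",
                    stars=float(stars),
                    provenance=f"{rec.mode}:{rec.level}",
                )
            )
    return records, skipped
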