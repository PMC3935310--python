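"""Calibration of sequence-based predictor output onto the star scale.

Two predictors are supported: a k-nearest-neighbour tool whose per-compartment
score v roughly counts supporting neighbours out of k (stars = 3 v / k), and a
naive-Bayes tool emitting posterior probabilities that pile up near 0 and 1
(stars = -log10(1 - p), so each extra nine of posterior adds one star).
Prediction stars are capped at three so that predictions can never outrank
reliable curated, experimental or literature evidence.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Mapping

from .errors import InputError, ValidationError
from .records import PredictionRecord

logger = logging.getLogger(__name__)

STAR_CAP = 3.0


def psort_stars(v: float, k: int = 32) -> float:
    """Stars for a k-NN score: linear in the supporting-neighbour fraction."""
    if k <= 0:
        raise ValidationError(f"neighbour count k must be positive, got {k}")
    if not (0 <= v <= k):
        raise ValidationError(f"k-NN score {v} outside [0, {k}]")
    return min(STAR_CAP, max(0.0, STAR_CAP * v / k))


def yloc_stars(p: float) -> float | None:
    """Stars for a posterior probability; ``None`` drops p <= 0.5.

    stars = min(3, -log10(1 - p)); p = 1 maps to the three-star cap.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"posterior {p} outside [0, 1]")
    if p <= 0.5:
        return None
    if p >= 1.0:
        return STAR_CAP
    return min(STAR_CAP, -math.log10(1.0 - p))


def import_predictions_tsv(
    path: str | Path,
    tool: str,
    label_map: Mapping[str, str] | None = None,
    default_k: int = 32,
) -> tuple[list[PredictionRecord], int]:
    """Read a predictor output TSV and calibrate to stars.

    Expected columns: ``protein``, ``location`` and ``score`` (plus ``k`` for
    the k-NN tool; *default_k* fills a missing column value but an absent
    column is an input error).  Location labels are routed through *label_map*
    when given; unmapped labels are skipped and counted.  Returns the records
    plus the skipped-row count (unmapped label or dropped low posterior).
    """
    if tool not in ("psort", "yloc"):
        raise ValidationError(f"unknown prediction tool {tool!r}")
    records: list[PredictionRecord] = []
    skipped = 0
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot read predictions {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if tool == "psort" and "k" not in cols:
            raise InputError(f"{path}: psort predictions require a 'k' column")
        for row in reader:
            label = row["location"]
            term = label_map.get(label, None) if label_map is not None else label
            if term is None:
                logger.warning("unmapped prediction label %r: skipped", label)
                skipped += 1
                continue
            raw = float(row["score"])
            if tool == "psort":
                k = int(row.get("k") or default_k)
                stars = psort_stars(raw, k)
            else:
                maybe = yloc_stars(raw)
                if maybe is None:
                    skipped += 1
                    continue
                stars = maybe
            records.append(
                PredictionRecord(
                    protein=row["protein"], term=term, tool=tool, raw=raw, stars=stars
                )
            )
    return records, skipped


def write_predictions_tsv(records: list[PredictionRecord], path: str | Path) -> None:
    """Calibrated prediction table: protein, term, tool, raw, stars."""
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tterm\ttool\traw\tstars\n")
        for r in sorted(records, key=lambda r: (r.protein, r.term, r.tool)):
            fh.write(f"{r.protein}\t{r.term}\t{r.tool}\t{r.raw:.6g}\t{r.stars:.6g}\n")
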