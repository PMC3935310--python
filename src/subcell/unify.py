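"""Identifier unification and cross-channel merging.

All channels are keyed to canonical protein identifiers through an alias
table (STRING-alias-style), projected to slim compartments, and merged under
the strongest-evidence rule: per (protein, compartment) the integrated
confidence is the maximum star score over channels.  Star values stay
continuous; bucketing into the 0-4 shade scale used by cell-schematic
visualizations happens only at display time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .ontology import OntologyGraph, SlimSet, backtrack
from .records import CHANNEL_CAPS, EvidenceRecord

logger = logging.getLogger(__name__)


@dataclass
class AliasTable:
    """Rows of (taxon, canonical protein id, alias, source tag)."""

    rows: list[tuple[str, str, str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("empty alias table")
        self._index: dict[tuple[str, str], set[str]] = {}
        for taxon, canonical, alias, _source in self.rows:
            if not canonical:
                raise ValidationError("empty canonical id in alias table")
            self._index.setdefault((taxon, alias), set()).add(canonical)
            # canonical ids resolve to themselves
            self._index.setdefault((taxon, canonical), set()).add(canonical)

    def resolve(self, taxon: str, alias: str) -> set[str]:
        return self._index.get((taxon, alias), set())

    def taxa(self) -> set[str]:
        return {t for t, _, _, _ in self.rows}


def read_alias_tsv(path: str | Path) -> AliasTable:
    """Alias TSV: taxon TAB canonical id TAB alias TAB source."""
    rows: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            taxon, canonical, alias, source = line.rstrip("\n").split("\t")
            rows.append((taxon, canonical, alias, source))
    return AliasTable(rows=rows)


@dataclass
class MappingStats:
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0


def map_aliases(
    records: Iterable[EvidenceRecord],
    aliases: AliasTable,
    taxon: str,
) -> tuple[list[EvidenceRecord], MappingStats]:
    """Re-key records to canonical protein ids.

    Aliases resolving to two or more canonical ids are dropped (precision
    over recall), as are aliases absent from the table; both are counted.
    """
    if taxon not in aliases.taxa():
        raise ValidationError(f"taxon {taxon!r} not present in alias table")
    out: list[EvidenceRecord] = []
    stats = MappingStats()
    for rec in records:
        canonicals = aliases.resolve(taxon, rec.protein)
        if not canonicals:
            stats.unmapped += 1
            continue
        if len(canonicals) > 1:
            stats.ambiguous += 1
            continue
        out.append(rec.with_protein(next(iter(canonicals))))
        stats.mapped += 1
    if stats.ambiguous or stats.unmapped:
        logger.info(
            "alias mapping: %d mapped, %d ambiguous dropped, %d unmapped dropped",
            stats.mapped, stats.ambiguous, stats.unmapped,
        )
    return out, stats


@dataclass
class UnifiedTable:
    """Per (protein, slim term): best stars per channel and overall."""

    cells: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def overall(self, protein: str, term: str) -> float | None:
        channels = self.cells.get((protein, term))
        return max(channels.values()) if channels else None

    def profile(self, protein: str) -> dict[str, float]:
        """Compartment profile: slim term -> overall stars for one protein."""
        return {
            term: max(ch.values())
            for (p, term), ch in self.cells.items()
            if p == protein
        }

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (protein, term), channels in sorted(self.cells.items()):
            row: dict[str, object] = {"protein": protein, "term": term}
            row.update(channels)
            row["overall"] = max(channels.values())
            rows.append(row)
        frame = pd.DataFrame(rows)
        if frame.empty:
            return frame
        ordered = ["protein", "term"] + [c for c in CHANNEL_CAPS if c in frame.columns]
        return frame[ordered + ["overall"]]


def unify(
    channel_records: Mapping[str, Iterable[EvidenceRecord]],
    graph: OntologyGraph,
    slim: SlimSet,
) -> UnifiedTable:
    """Backtrack every channel to slim level and merge by strongest evidence.

    The result is deterministic and independent of record order; a channel
    with no evidence for a cell simply does not participate in the maximum
    (no zero-imputation).
    """
    table = UnifiedTable()
    for channel in sorted(channel_records):
        recs = list(channel_records[channel])
        for rec in recs:
            if rec.channel != channel:
                raise ValidationError(
                    f"record channel {rec.channel!r} filed under {channel!r}"
                )
        for slim_rec in backtrack(recs, graph, slim):
            cell = table.cells.setdefault((slim_rec.protein, slim_rec.term), {})
            if slim_rec.stars > cell.get(channel, -1.0):
                cell[channel] = slim_rec.stars
    return table


def color_bucket(stars: float | None) -> int:
    """Shade index 0..4 for the cell schematic.

    0 is white (no evidence); confidence buckets darken from 1 to 4, with
    five-star evidence sharing the darkest bucket.
    """
    if stars is None or stars <= 0:
        return 0
    return min(4, math.ceil(stars))


def export_channel_tsv(
    records: Iterable[EvidenceRecord],
    path: str | Path,
    graph: OntologyGraph | None = None,
    protein_names: Mapping[str, str] | None = None,
) -> None:
    """Bulk-download-style channel file, stably sorted by (protein, term)."""
    names = protein_names or {}
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tprotein_name\tterm\tterm_name\tsource\tprovenance\tstars\n")
        for r in sorted(records, key=lambda r: (r.protein, r.term, r.source)):
            term_name = graph.name(r.term) if graph and r.term in graph else r.term
            fh.write(
                f"{r.protein}\t{names.get(r.protein, r.protein)}\t{r.term}\t"
                f"{term_name}\t{r.source}\t{r.provenance}\t{r.stars:.6g}\n"
            )


def export_integrated_tsv(
    table: UnifiedTable,
    path: str | Path,
    graph: OntologyGraph | None = None,
    protein_names: Mapping[str, str] | None = None,
) -> None:
    """Integrated slim-level file: protein, term, overall stars."""
    names = protein_names or {}
    with open(path, "w", newline="\n") as fh:
        fh.write("protein\tprotein_name\tterm\tterm_name\tstars\n")
        for (protein, term), channels in sorted(table.cells.items()):
            term_name = graph.name(term) if graph and term in graph else term
            fh.write(
                f"{protein}\t{names.get(protein, protein)}\t{term}\t{term_name}\t"
                f"{max(channels.values()):.6g}\n"
            )


def read_integrated_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_channel_tsv(path: str | Path, channel: str) -> list[EvidenceRecord]:
    """Read back a channel export written by :func:`export_channel_tsv`."""
    records: list[EvidenceRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                EvidenceRecord(
                    protein=f[idx["protein"]],
                    term=f[idx["term"]],
                    channel=channel,
                    source=f[idx["source"]],
                    stars=float(f[idx["stars"]]),
                    provenance=f[idx["provenance"]],
                )
            )
    return records


def links_from_integrated(frame: pd.DataFrame, min_stars_exclusive: float = 2.0) -> list[tuple[str, str]]:
    """Strict star filter applied to an integrated table read from disk."""
    kept = frame[frame["stars"] > min_stars_exclusive]
    return sorted(set(zip(kept["protein"], kept["term"])))
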