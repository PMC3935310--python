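"""Core record types shared by all evidence channels.

Every piece of localization evidence, whatever its origin, is normalised to
an :class:`EvidenceRecord`: one (protein, compartment term) assertion carrying
the evidence *channel* it came from, the source database or tool, a star
confidence in [0, 5] and free-text provenance (evidence code, z-score or raw
predictor score).  Channels have hard star caps: curated knowledge can reach
five stars, antibody-based experiments and text mining four, sequence-based
predictions three.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ValidationError

#: Star ceilings per evidence channel.
CHANNEL_CAPS: dict[str, float] = {
    "knowledge": 5.0,
    "experiments": 4.0,
    "textmining": 4.0,
    "predictions": 3.0,
}

CHANNELS = tuple(CHANNEL_CAPS)


@dataclass(frozen=True, slots=True)
class EvidenceRecord:
    """One (protein, compartment, channel) assertion with a star confidence."""

    protein: str
    term: str
    channel: str
    source: str
    stars: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_CAPS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        cap = CHANNEL_CAPS[self.channel]
        if not (0.0 <= self.stars <= cap + 1e-12):
            raise ValidationError(
                f"stars {self.stars} outside [0, {cap}] for channel {self.channel}"
            )

    def with_term(self, term: str) -> "EvidenceRecord":
        return replace(self, term=term)

    def with_protein(self, protein: str) -> "EvidenceRecord":
        return replace(self, protein=protein)


@dataclass(frozen=True, slots=True)
class CuratedAnnotation:
    """A curated annotation row before star scoring (GAF-style)."""

    protein: str
    term: str
    source: str
    evidence_code: str

    def __post_init__(self) -> None:
        if not self.evidence_code:
            raise ValidationError("evidence_code must be non-empty")


RELIABILITY_LEVELS = ("high", "medium", "low", "very low")
VALIDATION_LEVELS = ("supportive", "uncertain", "non-supportive")


@dataclass(frozen=True, slots=True)
class HpaRecord:
    """An antibody-screen record with an HPA-style quality level.

    ``mode`` selects which of the two quality scales applies: *reliability*
    (protein stained with two or more antibodies) or *validation* (single
    antibody).
    """

    protein: str
    location_label: str
    mode: str
    level: str
    antibody_count: int = 1

    def __post_init__(self) -> None:
        level = self.level.strip().lower()
        if self.mode == "reliability":
            if level not in RELIABILITY_LEVELS:
                raise ValidationError(f"bad reliability level {self.level!r}")
            if self.antibody_count < 2:
                raise ValidationError(
                    "reliability scoring requires two or more antibodies"
                )
        elif self.mode == "validation":
            if level not in VALIDATION_LEVELS:
                raise ValidationError(f"bad validation level {self.level!r}")
        else:
            raise ValidationError(f"unknown HPA mode {self.mode!r}")


@dataclass(frozen=True, slots=True)
class PredictionRecord:
    """A calibrated sequence-based prediction (stars capped at 3)."""

    protein: str
    term: str
    tool: str
    raw: float
    stars: float

    def __post_init__(self) -> None:
        if self.tool not in ("psort", "yloc"):
            raise ValidationError(f"unknown prediction tool {self.tool!r}")
        if self.stars > 3.0 + 1e-12 or self.stars < 0.0:
            raise ValidationError(f"prediction stars {self.stars} outside [0, 3]")
        if self.tool == "yloc" and not (0.0 <= self.raw <= 1.0):
            raise ValidationError("yloc posterior outside [0, 1]")
        if self.tool == "psort" and self.raw < 0:
            raise ValidationError("psort score must be non-negative")

    def to_evidence(self) -> EvidenceRecord:
        return EvidenceRecord(
            protein=self.protein,
            term=self.term,
            channel="predictions",
            source=self.tool,
            stars=self.stars,
            provenance=f"raw={self.raw:g}",
        )


@dataclass(frozen=True, slots=True)
class DocumentRecord:
    """A pre-segmented abstract: document id plus ordered sentences."""

    doc_id: str
    sentences: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValidationError(f"document {self.doc_id!r} has no sentences")
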