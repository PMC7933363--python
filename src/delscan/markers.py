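"""Marker anchoring from tabular alignment hits.

Places QTL/GBS markers on an assembly by picking each marker's best hit —
ranked by e-value, then bitscore, then alignment length — and accounts for
which markers map to one, both, or neither of two genomes. Candidate genes
under a placed interval come from an annotation interval query.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import Annotation, GeneModel, GenomicInterval

__all__ = [
    "MarkerHit",
    "MarkerPlacement",
    "top_hit",
    "place_markers",
    "dual_genome_summary",
    "genes_in_interval",
]


@dataclass(frozen=True)
class MarkerHit:
    """One row of a 12-column tabular alignment (subject coords 1-based;
    send < sstart indicates a minus-strand hit)."""

    marker_id: str
    subject: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def strand(self) -> str:
        return "-" if self.send < self.sstart else "+"

    @property
    def interval(self) -> GenomicInterval:
        """Subject span normalized to start < end, 0-based half-open."""
        lo, hi = sorted((self.sstart, self.send))
        return GenomicInterval(self.subject, lo - 1, hi)


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    interval: GenomicInterval
    strand: str
    ambiguous: bool
    hit: MarkerHit


def top_hit(hits: Sequence[MarkerHit]) -> MarkerPlacement:
    """Best placement of one marker: min e-value, then max bitscore, then
    max alignment length; residual full ties resolve to the lexicographically
    smallest (subject, sstart) and are flagged ambiguous.
    """
    if not hits:
        raise ValueError("top_hit requires at least one hit")
    marker_ids = {h.marker_id for h in hits}
    if len(marker_ids) > 1:
        raise ValueError(f"mixed marker_ids in top_hit: {sorted(marker_ids)}")

    def rank_key(h: MarkerHit):
        return (h.evalue, -h.bitscore, -h.alignment_length)

    best_key = min(rank_key(h) for h in hits)
    tied = [h for h in hits if rank_key(h) == best_key]
    winner = min(tied, key=lambda h: (h.subject, h.sstart))
    return MarkerPlacement(
        marker_id=winner.marker_id,
        interval=winner.interval,
        strand=winner.strand,
        ambiguous=len(tied) > 1,
        hit=winner,
    )


def place_markers(
    hits: Sequence[MarkerHit],
    min_identity: Optional[float] = None,
    max_evalue: Optional[float] = None,
) -> dict[str, MarkerPlacement]:
    """Top-hit placement for every marker present in *hits*.

    No identity or e-value cutoff is applied by default; the optional
    thresholds drop hits before ranking (a marker whose hits are all dropped
    is absent from the result, i.e. unmapped).
    """
    by_marker: dict[str, list[MarkerHit]] = {}
    for h in hits:
        if min_identity is not None and h.percent_identity < min_identity:
            continue
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        by_marker.setdefault(h.marker_id, []).append(h)
    return {m: top_hit(hs) for m, hs in sorted(by_marker.items())}


def dual_genome_summary(
    placements_a: Mapping[str, MarkerPlacement],
    placements_b: Mapping[str, MarkerPlacement],
    all_markers: Sequence[str],
) -> dict[str, int]:
    """Four disjoint mapped/unmapped counts over the marker universe.

    Absence from a placement map means the marker did not map to that
    genome. Returns ``{"both", "a_only", "b_only", "neither"}`` summing to
    the universe size.
    """
    universe = set(all_markers)
    if len(universe) != len(all_markers):
        raise ValueError("duplicate marker ids in all_markers")
    stray = (set(placements_a) | set(placements_b)) - universe
    if stray:
        raise ValueError(f"placements for markers not in universe: {sorted(stray)}")
    in_a = set(placements_a)
    in_b = set(placements_b)
    return {
        "both": len(in_a & in_b),
        "a_only": len(in_a - in_b),
        "b_only": len(in_b - in_a),
        "neither": len(universe - in_a - in_b),
    }


def genes_in_interval(
    interval: GenomicInterval, annotation: Annotation
) -> list[GeneModel]:
    """All genes whose span overlaps *interval* by >= 1 bp, sorted by start.

    Used to list candidate genes under a QTL support interval.
    """
    return annotation.overlapping(interval)
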