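"""Core domain types shared by every pipeline stage.

All internal coordinates are 0-based half-open ``[start, end)``. Conversion to
and from the 1-based conventions of VCF and GFF3 happens only in
:mod:`delscan.io`, never downstream.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Genotype",
    "DeletionCall",
    "GeneModel",
    "Annotation",
    "PipelineParams",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0


class Genotype(enum.Enum):
    """Diploid state of a sample at a deletion site.

    MISSING contributes to no allele counts anywhere in the pipeline.
    """

    REF_REF = "0/0"
    REF_DEL = "0/1"
    DEL_DEL = "1/1"
    MISSING = "./."

    @property
    def alt_alleles(self) -> int:
        """Deleted-allele dosage; MISSING and REF_REF count zero."""
        if self is Genotype.REF_DEL:
            return 1
        if self is Genotype.DEL_DEL:
            return 2
        return 0

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.REF_DEL, Genotype.DEL_DEL)


@dataclass(frozen=True)
class DeletionCall:
    """One caller's deletion call for one sample."""

    interval: GenomicInterval
    sample_id: str
    caller_id: str
    genotype: Genotype
    qual: Optional[float] = None
    record_id: str = "."

    def __post_init__(self) -> None:
        if not self.caller_id:
            raise ValueError("caller_id must be non-empty")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span, strand and ordered non-overlapping exons."""

    gene_id: str
    gene_name: str
    biotype: str
    span: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise ValueError(
                    f"exon chromosome {exon.chrom} differs from gene span "
                    f"{self.span.chrom} for {self.gene_id}"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(
                    f"exon [{exon.start}, {exon.end}) outside span of "
                    f"{self.gene_id}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"exons of {self.gene_id} unsorted or overlapping"
                )
            prev_end = exon.end

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"


class Annotation:
    """Indexed collection of :class:`GeneModel` for interval queries.

    Two per-chromosome interval indexes are kept: one over gene spans and one
    over spans extended by a regulatory flank on both sides. The flanked index
    is built lazily per flank size.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)
        )
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
        self._span_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._span_index.setdefault(g.span.chrom, IntervalTree())
            tree.addi(g.span.start, g.span.end, g)
        self._flank_index: dict[int, dict[str, IntervalTree]] = {}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._span_index)

    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        """Genes whose span shares >= 1 bp with *interval*, sorted by start."""
        tree = self._span_index.get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        return sorted(hits, key=lambda g: (g.span.start, g.gene_id))

    def _flanked(self, flank: int) -> dict[str, IntervalTree]:
        if flank not in self._flank_index:
            trees: dict[str, IntervalTree] = {}
            for g in self.genes:
                tree = trees.setdefault(g.span.chrom, IntervalTree())
                tree.addi(
                    max(0, g.span.start - flank), g.span.end + flank, g
                )
            self._flank_index[flank] = trees
        return self._flank_index[flank]

    def overlapping_flanked(
        self, interval: GenomicInterval, flank: int
    ) -> list[GeneModel]:
        """Genes whose flank-extended span shares >= 1 bp with *interval*."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        tree = self._flanked(flank).get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        return sorted(hits, key=lambda g: (g.span.start, g.gene_id))


@dataclass
class PipelineParams:
    """Tunable thresholds of the deletion pipeline.

    Defaults follow the analysis conditions: 50% reciprocal overlap for caller
    agreement, a 500 bp - 100 kb deletion size window, a 1000 bp regulatory
    flank, a strict >5% allele-frequency gate for the gene catalog, and a 0.05
    significance level on BH-adjusted enrichment q-values.
    """

    ro_threshold: float = 0.5
    min_len: int = 500
    max_len: int = 100_000
    flank: int = 1000
    af_threshold: float = 0.05
    alpha: float = 0.05
    primary_caller: str = "manta"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.ro_threshold <= 1):
            raise ValueError(
                f"ro_threshold must be in (0, 1], got {self.ro_threshold}"
            )
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"need 0 < min_len <= max_len, got {self.min_len}, {self.max_len}"
            )
        if self.flank < 0:
            raise ValueError(f"flank must be >= 0, got {self.flank}")
        if not (0 <= self.af_threshold < 1):
            raise ValueError(
                f"af_threshold must be in [0, 1), got {self.af_threshold}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
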