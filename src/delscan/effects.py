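"""Genomic-effect classification of deletions against a gene annotation.

Each deletion is assigned one of four mutually exclusive classes by priority:
coding (>= 1 bp overlap with an exon of a protein-coding gene), intronic
(overlap with a protein-coding gene span but no exon), regulatory (within the
flank, by default 1000 bp up- or downstream of a protein-coding gene span,
strand-ignoring), or intergenic. The gene catalog collects protein-coding
genes whose body is hit by a deletion locus with maximum per-population
allele frequency strictly above the threshold (default 5%).
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

from .core import Annotation, GenomicInterval
from .consensus import DeletionLocus

logger = logging.getLogger(__name__)

__all__ = ["EffectClass", "Contact", "GeneHit", "classify", "genes_hit", "gene_catalog"]


class EffectClass(enum.Enum):
    CODING_EXON = "coding_exon"
    INTRONIC = "intronic"
    REGULATORY = "regulatory"
    INTERGENIC = "intergenic"


class Contact(enum.Enum):
    """How a deletion touches one gene, strongest category kept."""

    EXON = "exon"
    INTRON = "intron"
    FLANK = "flank"


_CONTACT_RANK = {Contact.EXON: 0, Contact.INTRON: 1, Contact.FLANK: 2}


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    gene_name: str
    locus: DeletionLocus
    contact: Contact
    max_af: float


def classify(
    interval: GenomicInterval,
    annotation: Annotation,
    flank: int = 1000,
    cds_mode: bool = False,
) -> EffectClass:
    """Effect class of one interval, priority coding > intronic > regulatory.

    *cds_mode* is accepted for annotations distinguishing CDS from exon; with
    the exon-level gene models used here it is equivalent to the default.
    """
    if interval.chrom not in annotation.chromosomes:
        logger.info("chromosome %s absent from annotation; intergenic", interval.chrom)
        return EffectClass.INTERGENIC
    body_hits = [g for g in annotation.overlapping(interval) if g.is_protein_coding]
    for gene in body_hits:
        for exon in gene.exons:
            if interval.overlap_bp(exon) >= 1:
                return EffectClass.CODING_EXON
    if body_hits:
        return EffectClass.INTRONIC
    flank_hits = [
        g
        for g in annotation.overlapping_flanked(interval, flank)
        if g.is_protein_coding
    ]
    if flank_hits:
        return EffectClass.REGULATORY
    return EffectClass.INTERGENIC


def genes_hit(
    locus: DeletionLocus, annotation: Annotation, flank: int = 1000
) -> list[GeneHit]:
    """All protein-coding genes touched by a locus, one hit per gene.

    Contact records the strongest category per gene (exon > intron > flank),
    derived from the locus representative interval.
    """
    interval = locus.representative
    hits: dict[str, GeneHit] = {}
    for gene in annotation.overlapping_flanked(interval, flank):
        if not gene.is_protein_coding:
            continue
        if interval.overlap_bp(gene.span) >= 1:
            contact = Contact.INTRON
            for exon in gene.exons:
                if interval.overlap_bp(exon) >= 1:
                    contact = Contact.EXON
                    break
        else:
            contact = Contact.FLANK
        hits[gene.gene_id] = GeneHit(
            gene.gene_id, gene.gene_name, locus, contact, locus.max_af
        )
    return sorted(hits.values(), key=lambda h: h.gene_id)


def gene_catalog(
    loci: Sequence[DeletionLocus],
    annotation: Annotation,
    af_threshold: float = 0.05,
    flank: int = 1000,
) -> list[GeneHit]:
    """Genes whose body is deleted at max per-population AF > *af_threshold*.

    Only EXON/INTRON contacts qualify; flank-only hits belong to the separate
    regulatory catalog (:func:`regulatory_catalog`). Each gene appears once,
    carrying its strongest contact and highest allele frequency across loci;
    the order is deterministic (chrom, gene start, gene_id).
    """
    return _catalog(loci, annotation, af_threshold, flank, body=True)


def regulatory_catalog(
    loci: Sequence[DeletionLocus],
    annotation: Annotation,
    af_threshold: float = 0.05,
    flank: int = 1000,
) -> list[GeneHit]:
    """Genes hit only through their regulatory flank at AF > threshold."""
    return _catalog(loci, annotation, af_threshold, flank, body=False)


def _catalog(loci, annotation, af_threshold, flank, body):
    best: dict[str, GeneHit] = {}
    for locus in loci:
        if locus.max_af <= af_threshold:
            continue
        for hit in genes_hit(locus, annotation, flank):
            wanted = (
                hit.contact in (Contact.EXON, Contact.INTRON)
                if body
                else hit.contact is Contact.FLANK
            )
            if not wanted:
                continue
            prev = best.get(hit.gene_id)
            if (
                prev is None
                or _CONTACT_RANK[hit.contact] < _CONTACT_RANK[prev.contact]
                or (
                    _CONTACT_RANK[hit.contact] == _CONTACT_RANK[prev.contact]
                    and hit.max_af > prev.max_af
                )
            ):
                best[hit.gene_id] = hit
    if not body:
        # a gene already in the body catalog is not flank-only
        body_ids = {h.gene_id for h in _catalog(loci, annotation, af_threshold, flank, True)}
        best = {gid: h for gid, h in best.items() if gid not in body_ids}
    gene_pos = {g.gene_id: (g.span.chrom, g.span.start) for g in annotation}
    return sorted(
        best.values(), key=lambda h: (*gene_pos[h.gene_id], h.gene_id)
    )


def effect_counts(
    loci: Sequence[DeletionLocus],
    annotation: Annotation,
    flank: int = 1000,
    sample_to_population=None,
) -> dict:
    """Count loci per effect class, overall and (optionally) per population.

    A locus counts toward a population when any sample of that population
    carries the deletion; the per-class counts over all loci always sum to
    the number of loci (exhaustive partition).
    """
    overall = {ec: 0 for ec in EffectClass}
    per_pop: dict[str, dict[EffectClass, int]] = {}
    if sample_to_population:
        for pop in sorted(set(sample_to_population.values())):
            per_pop[pop] = {ec: 0 for ec in EffectClass}
    for locus in loci:
        ec = classify(locus.representative, annotation, flank)
        overall[ec] += 1
        if sample_to_population:
            pops = {
                sample_to_population[s]
                for s, gt in locus.members.items()
                if gt.is_carrier
            }
            for pop in pops:
                per_pop[pop][ec] += 1
    return {"overall": overall, "per_population": per_pop}
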