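"""End-to-end orchestration of the deletion analysis.

Glues the stages together: size filtering and two-caller intersection per
sample, cross-sample locus clustering, effect classification, the
allele-frequency-filtered gene catalog, per-sample allelic-state tabulation,
caller-agreement correlation, and gene-set enrichment. Also provides the
truth-based evaluation used with simulated cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .consensus import (
    ConsensusDeletion,
    DeletionLocus,
    cluster_loci,
    intersect_callsets,
    reciprocal_overlap,
    size_filter,
)
from .core import DeletionCall, PipelineParams
from .effects import GeneHit, effect_counts, gene_catalog, regulatory_catalog
from .enrich import EnrichmentResult, enrich_databases
from .popstats import (
    PopulationSummary,
    SampleDeletionCounts,
    caller_count_correlation,
    per_sample_counts,
    population_summary,
)

__all__ = ["PipelineResult", "run_pipeline", "RecoveryReport", "evaluate_recovery"]


@dataclass
class PipelineResult:
    params: PipelineParams
    consensus: list[ConsensusDeletion]
    loci: list[DeletionLocus]
    effect_counts: dict
    catalog: list[GeneHit]
    regulatory: list[GeneHit]
    sample_counts: list[SampleDeletionCounts]
    summaries: list[PopulationSummary]
    r_squared: Optional[float]
    enrichment: list[EnrichmentResult] = field(default_factory=list)

    @property
    def catalog_gene_ids(self) -> list[str]:
        return [h.gene_id for h in self.catalog]


def run_pipeline(
    calls_by_caller: Mapping[str, Mapping[str, Sequence[DeletionCall]]],
    sample_to_population: Mapping[str, str],
    annotation=None,
    params: Optional[PipelineParams] = None,
    gene_set_databases: Optional[Mapping[str, Mapping]] = None,
    background_genes: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run the full analysis over two callers' per-sample call sets.

    ``calls_by_caller`` maps caller_id -> sample_id -> calls. The caller
    named by ``params.primary_caller`` contributes the consensus coordinates
    and genotypes; with the default params the first caller in sorted order
    is primary if the configured name is absent. Annotation-dependent stages
    are skipped when *annotation* is None, enrichment when no gene sets are
    given.
    """
    params = params or PipelineParams()
    callers = sorted(calls_by_caller)
    if len(callers) != 2:
        raise ValueError(f"exactly two callers required, got {callers}")
    if params.primary_caller in callers:
        primary_id = params.primary_caller
    else:
        primary_id = callers[0]
    secondary_id = next(c for c in callers if c != primary_id)

    filtered = {
        caller: {
            s: size_filter(list(calls), params.min_len, params.max_len)
            for s, calls in calls_by_caller[caller].items()
        }
        for caller in callers
    }
    consensus: list[ConsensusDeletion] = []
    samples = sorted(
        set(filtered[primary_id]) | set(filtered[secondary_id])
    )
    for sample in samples:
        consensus.extend(
            intersect_callsets(
                filtered[primary_id].get(sample, []),
                filtered[secondary_id].get(sample, []),
                params.ro_threshold,
            )
        )
    loci = cluster_loci(consensus, params.ro_threshold, sample_to_population)

    sample_counts = per_sample_counts(consensus, sample_to_population)
    summaries = population_summary(sample_counts)
    counts_a = {s: len(filtered[primary_id].get(s, [])) for s in sample_to_population}
    counts_b = {s: len(filtered[secondary_id].get(s, [])) for s in sample_to_population}
    r2 = (
        caller_count_correlation(counts_a, counts_b)
        if len(sample_to_population) >= 3
        else None
    )

    counts = {"overall": {}, "per_population": {}}
    catalog: list[GeneHit] = []
    regulatory: list[GeneHit] = []
    if annotation is not None:
        counts = effect_counts(loci, annotation, params.flank, sample_to_population)
        catalog = gene_catalog(loci, annotation, params.af_threshold, params.flank)
        regulatory = regulatory_catalog(
            loci, annotation, params.af_threshold, params.flank
        )

    enrichment: list[EnrichmentResult] = []
    if gene_set_databases and annotation is not None:
        background = (
            list(background_genes)
            if background_genes is not None
            else sorted(g.gene_id for g in annotation if g.is_protein_coding)
        )
        enrichment = enrich_databases(
            [h.gene_id for h in catalog],
            gene_set_databases,
            background,
            params.alpha,
        )

    return PipelineResult(
        params=params,
        consensus=consensus,
        loci=loci,
        effect_counts=counts,
        catalog=catalog,
        regulatory=regulatory,
        sample_counts=sample_counts,
        summaries=summaries,
        r_squared=r2,
        enrichment=enrichment,
    )


@dataclass
class RecoveryReport:
    """Truth-based evaluation of a pipeline run on a simulated cohort."""

    n_truth_in_range: int
    n_loci: int
    n_loci_recovered: int      # truth deletions matched by >= 1 locus
    n_false_loci: int          # loci matching no truth deletion
    n_carrier_genotypes: int   # in-range truth carrier genotypes (jitter-safe)
    n_carrier_recovered: int   # of those, present as a consensus call

    @property
    def locus_recovery(self) -> float:
        return self.n_loci_recovered / self.n_truth_in_range if self.n_truth_in_range else 0.0

    @property
    def genotype_recovery(self) -> float:
        return self.n_carrier_recovered / self.n_carrier_genotypes if self.n_carrier_genotypes else 0.0


def evaluate_recovery(
    truth,
    result: PipelineResult,
    params: Optional[PipelineParams] = None,
    jitter_margin: int = 0,
) -> RecoveryReport:
    """Match pipeline output back to truth deletions by reciprocal overlap.

    A truth deletion is recovered when some locus overlaps it reciprocally at
    >= the threshold; a locus is false when it matches no truth. The
    genotype-level tally restricts to truth deletions whose length stays
    inside the size window under worst-case jitter (margin = 2 x jitter_bp
    per caller pair), where per-carrier recovery is an exact Bernoulli event.
    """
    params = params or result.params
    in_range = [
        t for t in truth if params.min_len <= t.interval.length <= params.max_len
    ]
    recovered = 0
    for t in in_range:
        if any(
            reciprocal_overlap(t.interval, l.representative) >= params.ro_threshold
            for l in result.loci
        ):
            recovered += 1
    false_loci = 0
    for l in result.loci:
        if not any(
            reciprocal_overlap(t.interval, l.representative) >= params.ro_threshold
            for t in truth
        ):
            false_loci += 1

    safe = [
        t
        for t in in_range
        if params.min_len + jitter_margin <= t.interval.length <= params.max_len - jitter_margin
    ]
    consensus_by_sample: dict[str, list] = {}
    for c in result.consensus:
        consensus_by_sample.setdefault(c.sample_id, []).append(c)
    n_carriers = 0
    n_recovered = 0
    for t in safe:
        for sample in t.carriers:
            n_carriers += 1
            for c in consensus_by_sample.get(sample, []):
                if reciprocal_overlap(t.interval, c.interval) >= params.ro_threshold:
                    n_recovered += 1
                    break
    return RecoveryReport(
        n_truth_in_range=len(in_range),
        n_loci=len(result.loci),
        n_loci_recovered=recovered,
        n_false_loci=false_loci,
        n_carrier_genotypes=n_carriers,
        n_carrier_recovered=n_recovered,
    )
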