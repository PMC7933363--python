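"""Per-sample allelic-state tabulation and population summaries.

For each individual, count deletions carried heterozygously (one deleted
haplotype) or homozygously (both); summarise per population with the sample
standard deviation (n-1). The caller-agreement statistic is the squared
Pearson correlation of the two callers' per-sample raw deletion counts.
"""
from __future__ import annotations

import enum

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .consensus import ConsensusDeletion
from .core import Genotype

__all__ = [
    "AlleleState",
    "allele_state",
    "SampleDeletionCounts",
    "PopulationSummary",
    "per_sample_counts",
    "population_summary",
    "caller_count_correlation",
]


class AlleleState(enum.Enum):
    HET = "het"
    HOM = "hom"
    NONE = "none"


def allele_state(g: Genotype) -> AlleleState:
    if g is Genotype.REF_DEL:
        return AlleleState.HET
    if g is Genotype.DEL_DEL:
        return AlleleState.HOM
    return AlleleState.NONE


@dataclass(frozen=True)
class SampleDeletionCounts:
    sample_id: str
    population_id: str
    n_het: int
    n_hom: int

    @property
    def total(self) -> int:
        return self.n_het + self.n_hom


@dataclass(frozen=True)
class PopulationSummary:
    population_id: str
    n_samples: int
    het_mean: float
    het_sd: Optional[float]
    hom_mean: float
    hom_sd: Optional[float]


def per_sample_counts(
    consensus: Sequence[ConsensusDeletion],
    sample_to_population: Mapping[str, str],
) -> list[SampleDeletionCounts]:
    """One row per mapped sample (zero rows permitted), sorted by sample."""
    missing = {c.sample_id for c in consensus} - set(sample_to_population)
    if missing:
        raise ValueError(f"consensus samples not in population map: {sorted(missing)}")
    het: dict[str, int] = {s: 0 for s in sample_to_population}
    hom: dict[str, int] = {s: 0 for s in sample_to_population}
    for c in consensus:
        state = allele_state(c.genotype)
        if state is AlleleState.HET:
            het[c.sample_id] += 1
        elif state is AlleleState.HOM:
            hom[c.sample_id] += 1
    return [
        SampleDeletionCounts(s, sample_to_population[s], het[s], hom[s])
        for s in sorted(sample_to_population)
    ]


def population_summary(
    counts: Sequence[SampleDeletionCounts],
) -> list[PopulationSummary]:
    """Mean and sample SD (n-1) of het/hom counts per population.

    Single-sample populations report the SD as None (undefined).
    """
    by_pop: dict[str, list[SampleDeletionCounts]] = {}
    for c in counts:
        by_pop.setdefault(c.population_id, []).append(c)
    out = []
    for pop in sorted(by_pop):
        rows = by_pop[pop]
        hets = np.array([r.n_het for r in rows], dtype=float)
        homs = np.array([r.n_hom for r in rows], dtype=float)
        n = len(rows)
        out.append(
            PopulationSummary(
                population_id=pop,
                n_samples=n,
                het_mean=float(hets.mean()),
                het_sd=float(hets.std(ddof=1)) if n > 1 else None,
                hom_mean=float(homs.mean()),
                hom_sd=float(homs.std(ddof=1)) if n > 1 else None,
            )
        )
    return out


def caller_count_correlation(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> Optional[float]:
    """Squared Pearson correlation of per-sample call counts of two callers.

    The two mappings are paired by sample id (keys must agree, n >= 3).
    Returns None when either vector has zero variance.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("caller count tables have different sample sets")
    samples = sorted(counts_a)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(samples)}")
    a = np.array([counts_a[s] for s in samples], dtype=float)
    b = np.array([counts_b[s] for s in samples], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
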