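"""Two-caller consensus and cross-sample deletion loci.

A deletion is accepted when both callers report it for the same sample with a
reciprocal overlap of at least the threshold (default 50% of the length of
each call), within the 500 bp - 100 kb size window. Consensus deletions are
then clustered across samples by single-linkage at the same reciprocal-overlap
threshold into loci, from which per-population allele frequencies are
computed.
"""
from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import DeletionCall, GenomicInterval, Genotype

logger = logging.getLogger(__name__)

__all__ = [
    "reciprocal_overlap",
    "size_filter",
    "intersect_callsets",
    "cluster_loci",
    "ConsensusDeletion",
    "DeletionLocus",
]


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Symmetric overlap fraction min(ov/len(a), ov/len(b)) in [0, 1].

    Different chromosomes give 0 by contract.
    """
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def size_filter(
    calls: Sequence[DeletionCall], min_len: int = 500, max_len: int = 100_000
) -> list[DeletionCall]:
    """Keep calls with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [c for c in calls if min_len <= c.length <= max_len]
    removed = len(calls) - len(kept)
    if removed:
        logger.info("size filter removed %d of %d calls", removed, len(calls))
    return kept


@dataclass(frozen=True)
class ConsensusDeletion:
    """A deletion supported by both callers for one sample.

    Coordinates and genotype come from the primary caller; the secondary
    caller's genotype is used only when the primary genotype is missing.
    """

    interval: GenomicInterval
    sample_id: str
    genotype: Genotype
    matched_ro: float
    source_ids: tuple[str, str]
    callers: tuple[str, str] = ("primary", "secondary")

    @property
    def length(self) -> int:
        return self.interval.length


def intersect_callsets(
    primary: Sequence[DeletionCall],
    secondary: Sequence[DeletionCall],
    ro_threshold: float = 0.5,
) -> list[ConsensusDeletion]:
    """One sample's two-caller intersection by greedy reciprocal overlap.

    Each primary call is retained iff at least one not-yet-consumed secondary
    call on the same chromosome overlaps it reciprocally by >= *ro_threshold*.
    Candidate pairs are matched greedily in descending overlap; ties break on
    smaller |start difference|, then smaller secondary start. Each secondary
    call supports at most one primary call. The result carries the primary
    caller's coordinates, sorted by position.
    """
    samples = {c.sample_id for c in primary} | {c.sample_id for c in secondary}
    if len(samples) > 1:
        raise ValueError(f"mixed sample_ids in intersect_callsets: {sorted(samples)}")

    # candidate pairs above threshold, per chromosome
    sec_by_chrom: dict[str, list[tuple[int, DeletionCall]]] = {}
    for j, s in enumerate(secondary):
        sec_by_chrom.setdefault(s.interval.chrom, []).append((j, s))
    pairs = []  # (-ro, |dstart|, sec_start, prim_idx, sec_idx)
    for i, p in enumerate(primary):
        for j, s in sec_by_chrom.get(p.interval.chrom, []):
            ro = reciprocal_overlap(p.interval, s.interval)
            if ro >= ro_threshold:
                pairs.append(
                    (
                        -ro,
                        abs(p.interval.start - s.interval.start),
                        s.interval.start,
                        # residual keys: physical coordinates, so the greedy
                        # order never depends on input ordering
                        p.interval.start,
                        p.interval.end,
                        s.interval.end,
                        i,
                        j,
                    )
                )
    pairs.sort(key=lambda t: t[:6])

    used_primary: dict[int, tuple[float, int]] = {}
    used_secondary: set[int] = set()
    for neg_ro, _dstart, _sstart, *_rest, i, j in pairs:
        if i in used_primary or j in used_secondary:
            continue
        used_primary[i] = (-neg_ro, j)
        used_secondary.add(j)

    out = []
    for i, (ro, j) in used_primary.items():
        p, s = primary[i], secondary[j]
        genotype = p.genotype if p.genotype is not Genotype.MISSING else s.genotype
        out.append(
            ConsensusDeletion(
                interval=p.interval,
                sample_id=p.sample_id,
                genotype=genotype,
                matched_ro=ro,
                source_ids=(p.record_id, s.record_id),
                callers=(p.caller_id, s.caller_id),
            )
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


@dataclass
class DeletionLocus:
    """A cross-sample cluster of consensus deletions.

    The representative interval is the component-wise median of member starts
    and ends (ties toward the smaller value). ``members`` maps each sample
    carrying a consensus call to its genotype; ``population_af`` holds the
    deleted-allele frequency per population, with samples lacking a call
    counted as homozygous reference and MISSING genotypes excluded from the
    denominator.
    """

    representative: GenomicInterval
    members: dict[str, Genotype]
    population_af: dict[str, float] = field(default_factory=dict)
    member_intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def max_af(self) -> float:
        return max(self.population_af.values(), default=0.0)


def _low_median(values: list[int]) -> int:
    """Median with even-count ties resolved toward the smaller value."""
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def cluster_loci(
    consensus: Sequence[ConsensusDeletion],
    ro_threshold: float = 0.5,
    sample_to_population: Optional[Mapping[str, str]] = None,
) -> list[DeletionLocus]:
    """Single-linkage clustering of consensus deletions into loci.

    Two calls are linked when their reciprocal overlap is >= *ro_threshold*;
    loci are the connected components. Allele frequencies use a per-population
    denominator of 2 x (samples with a non-MISSING genotype at the locus);
    cohort samples without a call at the locus count as homozygous reference.
    """
    if sample_to_population is not None:
        missing = {c.sample_id for c in consensus} - set(sample_to_population)
        if missing:
            raise ValueError(
                f"samples not in population map: {sorted(missing)}"
            )

    n = len(consensus)
    order = sorted(
        range(n),
        key=lambda i: (
            consensus[i].interval.chrom,
            consensus[i].interval.start,
            consensus[i].interval.end,
        ),
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # sweep: compare each call only against earlier calls that can still
    # overlap it (sorted by start within chromosome)
    active: list[int] = []
    prev_chrom = None
    for idx in order:
        iv = consensus[idx].interval
        if iv.chrom != prev_chrom:
            active = []
            prev_chrom = iv.chrom
        active = [k for k in active if consensus[k].interval.end > iv.start]
        for k in active:
            if reciprocal_overlap(iv, consensus[k].interval) >= ro_threshold:
                union(idx, k)
        active.append(idx)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    loci = []
    for comp in components.values():
        calls = [consensus[i] for i in comp]
        chrom = calls[0].interval.chrom
        rep = GenomicInterval(
            chrom,
            _low_median([c.interval.start for c in calls]),
            _low_median([c.interval.end for c in calls]),
        )
        members: dict[str, Genotype] = {}
        member_intervals: dict[str, GenomicInterval] = {}
        for c in sorted(calls, key=lambda c: c.sample_id):
            if c.sample_id in members:
                # same sample twice in one component: keep the more deleted state
                if c.genotype.alt_alleles <= members[c.sample_id].alt_alleles:
                    continue
            members[c.sample_id] = c.genotype
            member_intervals[c.sample_id] = c.interval
        locus = DeletionLocus(rep, members, {}, member_intervals)
        if sample_to_population is not None:
            locus.population_af = _population_af(members, sample_to_population)
        loci.append(locus)
    loci.sort(key=lambda l: (l.representative.chrom, l.representative.start, l.representative.end))
    return loci


def _population_af(
    members: Mapping[str, Genotype], sample_to_population: Mapping[str, str]
) -> dict[str, float]:
    pops = sorted(set(sample_to_population.values()))
    af = {}
    for pop in pops:
        alt = 0
        n_called = 0
        for sample, sample_pop in sample_to_population.items():
            if sample_pop != pop:
                continue
            gt = members.get(sample, Genotype.REF_REF)  # no call => REF_REF
            if gt is Genotype.MISSING:
                continue
            n_called += 1
            alt += gt.alt_alleles
        af[pop] = alt / (2 * n_called) if n_called else 0.0
    return af
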