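"""Synthetic cohort generator for the deletion pipeline.

Emulates the statistical structure the analysis assumes: a gene annotation, a
set of truth deletions with planted effect classes and per-population allele
frequencies (genotypes drawn under Hardy-Weinberg), and two caller-flavored
call sets over those truths. The two caller profiles differ the way
short-read SV callers do — one calls many short false positives, the other
few long ones — with uniform breakpoint jitter and per-sample dropouts.

False positives are rejection-sampled so that no false positive reciprocally
overlaps any truth deletion (or the other caller's false positives for the
same sample) at or above the consensus threshold, which makes the two-caller
intersection free of false loci by construction and ground-truth
precision/recall exactly computable. Truth deletions are likewise mutually
separated below the threshold so cross-sample clustering maps loci onto
truths one-to-one. Everything is deterministic given the seed.
"""
from __future__ import annotations

import zlib
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as dio
from .core import Annotation, DeletionCall, GeneModel, GenomicInterval, Genotype
from .effects import Contact, EffectClass, classify, genes_hit
from .consensus import DeletionLocus

__all__ = [
    "CallerProfile",
    "TruthDeletion",
    "SimConfig",
    "simulate_annotation",
    "simulate_truth",
    "emit_caller_vcfs",
    "simulate_gmt",
    "simulate_cohort",
    "CohortData",
    "truth_in_range",
    "truth_loci",
]

_MAX_TRIES = 20_000


@dataclass
class CallerProfile:
    """Error model of one simulated SV caller."""

    caller_id: str
    sensitivity: float = 0.85
    fp_per_sample: float = 30.0
    fp_size_log10_mean: float = 2.9
    fp_size_log10_sd: float = 0.35
    jitter_bp: int = 50
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1):
            raise ValueError("sensitivity must be in [0, 1]")
        if not (0 <= self.genotype_error_rate <= 1):
            raise ValueError("genotype_error_rate must be in [0, 1]")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")


def default_profiles() -> list[CallerProfile]:
    """Two contrasting callers: a short-FP-heavy one and a long-FP-light one."""
    return [
        CallerProfile("lumpy", sensitivity=0.85, fp_per_sample=30.0,
                      fp_size_log10_mean=2.9),
        CallerProfile("manta", sensitivity=0.80, fp_per_sample=8.0,
                      fp_size_log10_mean=3.6),
    ]


@dataclass
class TruthDeletion:
    interval: GenomicInterval
    effect_class_planted: EffectClass
    population_af: dict[str, float]          # realized sample AF per population
    genotypes: dict[str, Genotype]           # per-sample, HWE given drawn AF
    deletion_id: str = ""

    @property
    def carriers(self) -> list[str]:
        return sorted(s for s, g in self.genotypes.items() if g.is_carrier)


@dataclass
class SimConfig:
    """All knobs of the generator; one seed drives every random draw."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000,
                                 "chr3": 10_000_000}
    )
    n_genes: int = 300
    noncoding_fraction: float = 0.1
    gene_len_range: tuple[int, int] = (2_000, 20_000)
    gene_gap_range: tuple[int, int] = (10_000, 60_000)
    populations: dict[str, int] = field(
        default_factory=lambda: {"Pachon": 8, "Tinaja": 8, "RioChoy": 8}
    )
    n_truth_deletions: int = 300
    truth_size_range: tuple[int, int] = (100, 200_000)
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            "coding_exon": 0.25, "intronic": 0.25,
            "regulatory": 0.20, "intergenic": 0.30,
        }
    )
    af_beta: tuple[float, float] = (0.6, 2.4)
    flank: int = 1000
    ro_threshold: float = 0.5
    caller_profiles: list[CallerProfile] = field(default_factory=default_profiles)
    # planted-enrichment gene sets
    n_gene_sets: int = 20
    gene_set_size: int = 50
    planted_set_fraction: float = 0.8  # fraction of the planted set drawn from catalog genes
    af_threshold: float = 0.05
    hard_mode: bool = False  # lift the FP/truth separation constraint

    def __post_init__(self) -> None:
        if self.n_truth_deletions < 0 or self.n_genes < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.truth_size_range
        if not (0 < lo <= hi):
            raise ValueError("truth_size_range must be positive and ordered")
        total = sum(self.effect_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"effect_mix must sum to 1, sums to {total}")

    @property
    def samples(self) -> list[str]:
        return [
            f"{pop}_{i:02d}"
            for pop in sorted(self.populations)
            for i in range(1, self.populations[pop] + 1)
        ]

    @property
    def sample_to_population(self) -> dict[str, str]:
        return {
            f"{pop}_{i:02d}": pop
            for pop in sorted(self.populations)
            for i in range(1, self.populations[pop] + 1)
        }


def _rng(config_seed: int, *tags: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the one config seed."""
    keys = [config_seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> Annotation:
    """Non-overlapping genes with 2-8 exons each, deterministic per seed."""
    rng = _rng(config.seed, "annotation")
    chroms = sorted(config.chrom_sizes)
    genes: list[GeneModel] = []
    # spread genes round-robin proportional to chromosome size
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    shares = np.floor(sizes / sizes.sum() * config.n_genes).astype(int)
    while shares.sum() < config.n_genes:
        shares[int(np.argmax(sizes - shares))] += 1
    gid = 0
    for chrom, share in zip(chroms, shares):
        cursor = int(rng.integers(*config.gene_gap_range))
        for _ in range(share):
            length = int(rng.integers(*config.gene_len_range))
            if cursor + length > config.chrom_sizes[chrom]:
                raise ValueError(
                    f"cannot place {config.n_genes} genes: chromosome {chrom} "
                    f"too small; enlarge chrom_sizes or reduce n_genes"
                )
            gid += 1
            span = GenomicInterval(chrom, cursor, cursor + length)
            biotype = (
                "lncRNA"
                if rng.random() < config.noncoding_fraction
                else "protein_coding"
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    gene_name=f"g{gid:04d}",
                    biotype=biotype,
                    span=span,
                    strand=strand,
                    exons=_random_exons(rng, span),
                )
            )
            cursor += length + int(rng.integers(*config.gene_gap_range))
    return Annotation(genes)


def _random_exons(rng: np.random.Generator, span: GenomicInterval) -> tuple:
    n_exons = int(rng.integers(2, 9))
    # 2*n_exons boundaries; first/last exon flush with the gene span
    inner = np.sort(
        rng.choice(np.arange(1, span.length), size=2 * n_exons - 2, replace=False)
    )
    bounds = np.concatenate([[0], inner, [span.length]])
    exons = []
    for i in range(0, 2 * n_exons, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e > s:
            exons.append(GenomicInterval(span.chrom, span.start + s, span.start + e))
    return tuple(exons)


# ---------------------------------------------------------------------------
# truth deletions


class _SeparationIndex:
    """Per-chromosome index rejecting intervals that could reach the
    reciprocal-overlap threshold against a stored interval.

    ``pad_stored`` / ``pad_query`` are worst-case breakpoint-jitter margins:
    the clash test bounds the overlap from above (both intervals expanded by
    their pad) and the lengths from below (shrunk by twice the pad), so if it
    passes, no jittered realization of either interval can reach the
    threshold.
    """

    def __init__(self, ro_threshold: float, pad_stored: int = 0, pad_query: int = 0):
        self.ro = ro_threshold
        self.ps = pad_stored
        self.pq = pad_query
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def clashes(self, iv: GenomicInterval) -> bool:
        entries = self.by_chrom.get(iv.chrom, [])
        if not entries:
            return False
        starts = [s for s, _ in entries]
        idx = bisect_left(starts, iv.end + self.ps + self.pq)
        len_q = max(1, iv.length - 2 * self.pq)
        # a clashing stored interval cannot start further back than this
        reach = (
            self.ps + self.pq
            + (iv.length + 2 * self.ps + 2 * self.pq) / self.ro
            + 2 * self.ps + 1
        )
        for s, e in reversed(entries[:idx]):
            if iv.start - s > reach:
                break
            ov = min(iv.end + self.pq, e + self.ps) - max(iv.start - self.pq, s - self.ps)
            if ov <= 0:
                continue
            len_s = max(1, (e - s) - 2 * self.ps)
            if min(ov / len_q, ov / len_s) >= self.ro:
                return True
        return False

    def add(self, iv: GenomicInterval) -> None:
        entries = self.by_chrom.setdefault(iv.chrom, [])
        starts = [s for s, _ in entries]
        entries.insert(bisect_left(starts, iv.start), (iv.start, iv.end))


def _class_targets(config: SimConfig) -> list[EffectClass]:
    counts = {}
    for name, frac in config.effect_mix.items():
        counts[EffectClass(name)] = int(np.floor(frac * config.n_truth_deletions))
    order = sorted(config.effect_mix, key=lambda k: -config.effect_mix[k])
    i = 0
    while sum(counts.values()) < config.n_truth_deletions:
        counts[EffectClass(order[i % len(order)])] += 1
        i += 1
    plan = []
    for ec in EffectClass:
        plan.extend([ec] * counts.get(ec, 0))
    return plan


def _draw_size(rng, lo: int, hi: int) -> int:
    return int(round(10 ** rng.uniform(np.log10(lo), np.log10(hi))))


def _propose_interval(
    rng, wanted: EffectClass, size: int, annotation: Annotation, config: SimConfig
) -> Optional[GenomicInterval]:
    """One targeted proposal for an interval of the wanted class."""
    chroms = sorted(config.chrom_sizes)
    coding = [g for g in annotation if g.is_protein_coding]
    if wanted is EffectClass.INTERGENIC or not coding:
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = config.chrom_sizes[chrom] - size
        if limit <= 0:
            return None
        start = int(rng.integers(0, limit))
        return GenomicInterval(chrom, start, start + size)
    gene = coding[int(rng.integers(len(coding)))]
    if wanted is EffectClass.CODING_EXON:
        exon = gene.exons[int(rng.integers(len(gene.exons)))]
        lo = max(0, exon.start - size + 1)
        hi = exon.end - 1
        if hi < lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        return GenomicInterval(exon.chrom, start, start + size)
    if wanted is EffectClass.INTRONIC:
        introns = [
            (a.end, b.start)
            for a, b in zip(gene.exons, gene.exons[1:])
            if b.start - a.end >= 3
        ]
        if not introns:
            return None
        s, e = introns[int(rng.integers(len(introns)))]
        if size > (e - s) - 2:  # must stay 1 bp clear of each exon
            return None
        start = int(rng.integers(s + 1, e - size))
        return GenomicInterval(gene.span.chrom, start, start + size)
    # REGULATORY: end just upstream of the span, or start just downstream
    if rng.random() < 0.5:
        end = gene.span.start - int(rng.integers(0, config.flank))
        start = end - size
        if start < 0:
            return None
    else:
        start = gene.span.end + int(rng.integers(0, config.flank))
        end = start + size
        if end > config.chrom_sizes[gene.span.chrom]:
            return None
    return GenomicInterval(gene.span.chrom, start, end)


def simulate_truth(
    annotation: Annotation, config: SimConfig
) -> list[TruthDeletion]:
    """Truth deletions realizing the configured effect-class mix.

    Placement is rejection sampling verified against :func:`effects.classify`,
    so the planted class always equals the classified class; pairwise
    reciprocal overlap between truths stays below the consensus threshold.
    Genotypes are Hardy-Weinberg draws from per-population Beta allele
    frequencies, redrawn until each deletion segregates in the cohort.
    """
    rng = _rng(config.seed, "truth")
    jmax = max((p.jitter_bp for p in config.caller_profiles), default=0)
    sep = _SeparationIndex(config.ro_threshold, pad_stored=jmax, pad_query=jmax)
    plan = _class_targets(config)
    lo, hi = config.truth_size_range
    a, b = config.af_beta
    s2p = config.sample_to_population
    truths: list[TruthDeletion] = []
    for i, wanted in enumerate(plan, 1):
        placed = None
        for _ in range(_MAX_TRIES):
            size = _draw_size(rng, lo, hi)
            iv = _propose_interval(rng, wanted, size, annotation, config)
            if iv is None or sep.clashes(iv):
                continue
            if classify(iv, annotation, config.flank) is wanted:
                placed = iv
                break
        if placed is None:
            raise ValueError(
                f"cannot realize effect class {wanted.value} after "
                f"{_MAX_TRIES} proposals; relax effect_mix or enlarge the genome"
            )
        sep.add(placed)
        drawn_af = {pop: float(rng.beta(a, b)) for pop in sorted(config.populations)}
        genotypes = _hwe_genotypes(rng, drawn_af, s2p)
        while not any(g.is_carrier for g in genotypes.values()):
            genotypes = _hwe_genotypes(rng, drawn_af, s2p)
        realized = {}
        for pop in sorted(config.populations):
            members = [s for s, p in s2p.items() if p == pop]
            alt = sum(genotypes[s].alt_alleles for s in members)
            realized[pop] = alt / (2 * len(members)) if members else 0.0
        truths.append(
            TruthDeletion(placed, wanted, realized, genotypes, f"del{i:04d}")
        )
    truths.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return truths


def _hwe_genotypes(rng, af_by_pop, sample_to_population) -> dict[str, Genotype]:
    out = {}
    for sample in sorted(sample_to_population):
        p = af_by_pop[sample_to_population[sample]]
        u = rng.random()
        if u < (1 - p) ** 2:
            out[sample] = Genotype.REF_REF
        elif u < (1 - p) ** 2 + 2 * p * (1 - p):
            out[sample] = Genotype.REF_DEL
        else:
            out[sample] = Genotype.DEL_DEL
    return out


# ---------------------------------------------------------------------------
# caller emission


def emit_caller_vcfs(
    truth: Sequence[TruthDeletion],
    profile: CallerProfile,
    config: SimConfig,
    out_dir: Optional[str | Path] = None,
    avoid_fp: Optional[dict[str, list[GenomicInterval]]] = None,
) -> tuple[dict[str, list[DeletionCall]], dict[str, list[GenomicInterval]]]:
    """Emit one caller's per-sample call sets (and optionally VCF files).

    Each carrier genotype is emitted with probability ``sensitivity``, its
    breakpoints shifted independently by uniform(-jitter, +jitter) clamped to
    length >= 1, and its genotype flipped HET<->HOM with
    ``genotype_error_rate``. False positives are Poisson per sample with
    lognormal sizes, placed so they reciprocally overlap no truth deletion
    and none of the intervals in *avoid_fp* (the other caller's false
    positives) at >= the consensus threshold, unless ``hard_mode`` is set.

    Returns (calls per sample, false-positive intervals per sample).
    """
    jmax = max((p.jitter_bp for p in config.caller_profiles), default=profile.jitter_bp)
    truth_sep = _SeparationIndex(config.ro_threshold, pad_stored=jmax)
    for t in truth:
        truth_sep.add(t.interval)
    calls: dict[str, list[DeletionCall]] = {}
    fps: dict[str, list[GenomicInterval]] = {}
    chroms = sorted(config.chrom_sizes)
    for sample in config.samples:
        rng = _rng(config.seed, "emit", profile.caller_id, sample)
        sample_calls: list[DeletionCall] = []
        for t in truth:
            gt = t.genotypes.get(sample, Genotype.REF_REF)
            if not gt.is_carrier:
                continue
            if rng.random() >= profile.sensitivity:
                continue
            iv = _jitter(rng, t.interval, profile.jitter_bp,
                         config.chrom_sizes[t.interval.chrom])
            if profile.genotype_error_rate and rng.random() < profile.genotype_error_rate:
                gt = (
                    Genotype.DEL_DEL if gt is Genotype.REF_DEL else Genotype.REF_DEL
                )
            sample_calls.append(
                DeletionCall(iv, sample, profile.caller_id, gt,
                             qual=float(np.round(rng.uniform(20, 60), 1)),
                             record_id=f"{profile.caller_id}_{sample}_{t.deletion_id}")
            )
        sample_fps: list[GenomicInterval] = []
        avoid = _SeparationIndex(config.ro_threshold)
        for iv in (avoid_fp or {}).get(sample, []):
            avoid.add(iv)
        n_fp = int(rng.poisson(profile.fp_per_sample))
        for j in range(n_fp):
            iv = _place_fp(rng, profile, config, chroms, truth_sep, avoid)
            sample_fps.append(iv)
            avoid.add(iv)
            sample_calls.append(
                DeletionCall(iv, sample, profile.caller_id, Genotype.REF_DEL,
                             qual=float(np.round(rng.uniform(20, 60), 1)),
                             record_id=f"{profile.caller_id}_{sample}_fp{j + 1}")
            )
        sample_calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
        calls[sample] = sample_calls
        fps[sample] = sample_fps
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            dio.write_deletion_vcf(
                sample_calls, out / f"{sample}.{profile.caller_id}.vcf", sample
            )
    return calls, fps


def _jitter(rng, iv: GenomicInterval, jitter_bp: int, chrom_size: int) -> GenomicInterval:
    if jitter_bp == 0:
        return iv
    start = iv.start + int(rng.integers(-jitter_bp, jitter_bp + 1))
    end = iv.end + int(rng.integers(-jitter_bp, jitter_bp + 1))
    start = max(0, start)
    end = min(chrom_size, max(end, start + 1))
    return GenomicInterval(iv.chrom, start, end)


def _place_fp(rng, profile, config, chroms, truth_sep, avoid) -> GenomicInterval:
    for _ in range(_MAX_TRIES):
        size = max(
            50,
            int(round(10 ** rng.normal(profile.fp_size_log10_mean,
                                       profile.fp_size_log10_sd))),
        )
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = config.chrom_sizes[chrom] - size
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        iv = GenomicInterval(chrom, start, start + size)
        if config.hard_mode or (not truth_sep.clashes(iv) and not avoid.clashes(iv)):
            return iv
    raise ValueError(
        "cannot place a false positive away from truth deletions; "
        "lower fp_per_sample or enlarge the genome"
    )


# ---------------------------------------------------------------------------
# gene sets and orchestration


def simulate_gmt(
    catalog_genes: Sequence[str],
    background: Sequence[str],
    config: SimConfig,
    tag: str = "gmt",
) -> list[dio.GeneSet]:
    """Random decoy gene sets plus one set enriched for catalog genes.

    The planted set draws ``planted_set_fraction`` of its members from the
    deletion gene catalog and the rest from the remaining background; decoys
    are uniform draws from the background.
    """
    rng = _rng(config.seed, tag)
    bg = sorted(set(background))
    catalog = sorted(set(catalog_genes) & set(bg))
    rest = sorted(set(bg) - set(catalog))
    size = min(config.gene_set_size, len(bg))
    sets = []
    n_from_catalog = min(int(round(config.planted_set_fraction * size)), len(catalog))
    planted = list(rng.choice(catalog, size=n_from_catalog, replace=False)) if n_from_catalog else []
    n_rest = min(size - n_from_catalog, len(rest))
    planted += list(rng.choice(rest, size=n_rest, replace=False))
    sets.append(dio.GeneSet("planted_set", "enriched for deletion genes",
                            frozenset(planted)))
    for i in range(1, config.n_gene_sets):
        members = rng.choice(bg, size=size, replace=False)
        sets.append(dio.GeneSet(f"decoy_{i:03d}", "random background draw",
                                frozenset(members)))
    return sets


def truth_in_range(
    truth: Sequence[TruthDeletion], min_len: int = 500, max_len: int = 100_000
) -> list[TruthDeletion]:
    return [t for t in truth if min_len <= t.interval.length <= max_len]


def truth_loci(truth: Sequence[TruthDeletion]) -> list[DeletionLocus]:
    """Truth deletions expressed as loci (carrier members only)."""
    loci = []
    for t in truth:
        members = {s: g for s, g in t.genotypes.items() if g.is_carrier}
        loci.append(
            DeletionLocus(t.interval, members, dict(t.population_af))
        )
    return loci


@dataclass
class CohortData:
    """Everything one simulated cohort produced, in memory."""

    config: SimConfig
    annotation: Annotation
    truth: list[TruthDeletion]
    calls: dict[str, dict[str, list[DeletionCall]]]  # caller -> sample -> calls
    false_positives: dict[str, dict[str, list[GenomicInterval]]]
    gene_sets: list[dio.GeneSet]

    @property
    def background_genes(self) -> list[str]:
        return sorted(g.gene_id for g in self.annotation if g.is_protein_coding)


def truth_gene_catalog(
    truth: Sequence[TruthDeletion],
    annotation: Annotation,
    af_threshold: float = 0.05,
    flank: int = 1000,
    min_len: int = 500,
    max_len: int = 100_000,
) -> list[str]:
    """Gene ids whose body is hit by an in-range truth deletion at
    max per-population AF strictly above the threshold."""
    genes: set[str] = set()
    for locus in truth_loci(truth_in_range(truth, min_len, max_len)):
        if max(locus.population_af.values(), default=0.0) <= af_threshold:
            continue
        for hit in genes_hit(locus, annotation, flank):
            if hit.contact in (Contact.EXON, Contact.INTRON):
                genes.add(hit.gene_id)
    return sorted(genes)


def simulate_cohort(
    config: SimConfig, out_dir: Optional[str | Path] = None
) -> CohortData:
    """Run the whole generator; optionally write GFF3/VCF/TSV/GMT artifacts."""
    if len(config.caller_profiles) != 2:
        raise ValueError("exactly two caller profiles are required")
    annotation = simulate_annotation(config)
    truth = simulate_truth(annotation, config)
    first, second = config.caller_profiles
    out = Path(out_dir) if out_dir is not None else None
    calls_a, fps_a = emit_caller_vcfs(
        truth, first, config, out / "vcf" if out else None
    )
    calls_b, fps_b = emit_caller_vcfs(
        truth, second, config, out / "vcf" if out else None, avoid_fp=fps_a
    )
    background = sorted(g.gene_id for g in annotation if g.is_protein_coding)
    catalog = truth_gene_catalog(truth, annotation, config.af_threshold, config.flank)
    gene_sets = simulate_gmt(catalog, background, config)
    cohort = CohortData(
        config=config,
        annotation=annotation,
        truth=truth,
        calls={first.caller_id: calls_a, second.caller_id: calls_b},
        false_positives={first.caller_id: fps_a, second.caller_id: fps_b},
        gene_sets=gene_sets,
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        dio.write_gff3(annotation, out / "annotation.gff3")
        dio.write_gmt(gene_sets, out / "gene_sets.gmt")
        _write_truth_tsv(truth, sorted(config.populations), out / "truth_deletions.tsv")
        _write_truth_genotypes(truth, config.samples, out / "truth_genotypes.tsv")
        with open(out / "truth_gene_catalog.txt", "w") as fh:
            fh.write("\n".join(catalog) + ("\n" if catalog else ""))
    return cohort


def _write_truth_tsv(truth, populations, path) -> None:
    with open(path, "w") as fh:
        header = ["deletion_id", "chrom", "start", "end", "length", "effect_class"]
        header += [f"af_{p}" for p in populations]
        fh.write("\t".join(header) + "\n")
        for t in truth:
            row = [
                t.deletion_id, t.interval.chrom, str(t.interval.start),
                str(t.interval.end), str(t.interval.length),
                t.effect_class_planted.value,
            ]
            row += [f"{t.population_af[p]:.6f}" for p in populations]
            fh.write("\t".join(row) + "\n")


def _write_truth_genotypes(truth, samples, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["deletion_id", *samples]) + "\n")
        for t in truth:
            row = [t.deletion_id] + [
                t.genotypes.get(s, Genotype.REF_REF).value for s in samples
            ]
            fh.write("\t".join(row) + "\n")
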