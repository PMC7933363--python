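"""Tabular artifact writers (TSV) for pipeline results."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .consensus import DeletionLocus
from .effects import GeneHit
from .enrich import EnrichmentResult
from .popstats import PopulationSummary, SampleDeletionCounts


def loci_table(loci: Sequence[DeletionLocus]) -> pd.DataFrame:
    pops = sorted({p for l in loci for p in l.population_af})
    rows = []
    for l in loci:
        row = {
            "chrom": l.representative.chrom,
            "start": l.representative.start,
            "end": l.representative.end,
            "length": l.representative.length,
            "n_members": l.n_members,
        }
        for p in pops:
            row[f"af_{p}"] = round(l.population_af.get(p, 0.0), 6)
        rows.append(row)
    return pd.DataFrame(rows)


def catalog_table(hits: Sequence[GeneHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "gene_name": h.gene_name,
                "contact": h.contact.value,
                "max_af": round(h.max_af, 6),
                "locus_chrom": h.locus.representative.chrom,
                "locus_start": h.locus.representative.start,
                "locus_end": h.locus.representative.end,
            }
            for h in hits
        ]
    )


def effect_counts_table(counts: dict) -> pd.DataFrame:
    rows = [
        {"population": "all", **{ec.value: n for ec, n in counts["overall"].items()}}
    ]
    for pop in sorted(counts.get("per_population", {})):
        rows.append(
            {
                "population": pop,
                **{ec.value: n for ec, n in counts["per_population"][pop].items()},
            }
        )
    return pd.DataFrame(rows)


def sample_counts_table(counts: Sequence[SampleDeletionCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "population": c.population_id,
                "n_het": c.n_het,
                "n_hom": c.n_hom,
            }
            for c in counts
        ]
    )


def population_summary_table(summaries: Sequence[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": s.population_id,
                "n_samples": s.n_samples,
                "het_mean": round(s.het_mean, 4),
                "het_sd": round(s.het_sd, 4) if s.het_sd is not None else "NA",
                "hom_mean": round(s.hom_mean, 4),
                "hom_sd": round(s.hom_sd, 4) if s.hom_sd is not None else "NA",
            }
            for s in summaries
        ]
    )


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "database": r.database,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": f"{r.p_value:.6g}",
                "q_value": f"{r.q_value:.6g}",
                "significant": r.significant,
            }
            for r in results
        ]
    )


def placements_table(placements: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_id": p.marker_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.strand,
                "ambiguous": p.ambiguous,
                "evalue": f"{p.hit.evalue:.3g}",
                "bitscore": p.hit.bitscore,
                "alignment_length": p.hit.alignment_length,
            }
            for _, p in sorted(placements.items())
        ]
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
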