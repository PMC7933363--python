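import numpy as np
import pytest

from delscan.core import Annotation, DeletionCall, GeneModel, GenomicInterval, Genotype


def make_gene(gene_id, chrom, start, end, exons, biotype="protein_coding", strand="+"):
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=biotype,
        span=GenomicInterval(chrom, start, end),
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


def make_call(chrom, start, end, sample="s1", caller="manta",
              genotype=Genotype.REF_DEL, record_id="."):
    return DeletionCall(
        GenomicInterval(chrom, start, end), sample, caller, genotype,
        record_id=record_id,
    )


def random_annotation(rng: np.random.Generator, n_genes=50, chrom_size=1_000_000,
                      chroms=("chr1", "chr2")) -> Annotation:
    """Random non-overlapping genes for oracle comparisons."""
    genes = []
    gid = 0
    for chrom in chroms:
        cursor = int(rng.integers(0, 5000))
        for _ in range(n_genes // len(chroms)):
            length = int(rng.integers(500, 8000))
            if cursor + length > chrom_size:
                break
            gid += 1
            n_ex = int(rng.integers(2, 5))
            inner = np.sort(rng.choice(np.arange(1, length), 2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[0], inner, [length]])
            exons = [
                (cursor + int(bounds[i]), cursor + int(bounds[i + 1]))
                for i in range(0, 2 * n_ex, 2)
                if bounds[i + 1] > bounds[i]
            ]
            genes.append(
                make_gene(
                    f"g{gid:03d}", chrom, cursor, cursor + length, exons,
                    biotype="protein_coding" if rng.random() > 0.15 else "lncRNA",
                )
            )
            cursor += length + int(rng.integers(2500, 20000))
    return Annotation(genes)


@pytest.fixture
def simple_annotation():
    """Two protein-coding genes and one lncRNA on one chromosome.

    geneA: [10_000, 20_000), exons [10_000, 11_000) and [19_000, 20_000)
    geneB: [50_000, 60_000), exons [50_000, 52_000) and [58_000, 60_000)
    ncrna: [80_000, 85_000), single exon
    """
    return Annotation(
        [
            make_gene("geneA", "chr1", 10_000, 20_000,
                      [(10_000, 11_000), (19_000, 20_000)]),
            make_gene("geneB", "chr1", 50_000, 60_000,
                      [(50_000, 52_000), (58_000, 60_000)]),
            make_gene("ncrna", "chr1", 80_000, 85_000,
                      [(80_000, 85_000)], biotype="lncRNA"),
        ]
    )
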