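"""Readers and writers for the standard formats the pipeline touches.

VCF (symbolic ``<DEL>`` and explicit-allele deletions), GFF3, BED, GMT gene
sets and 12-column BLAST-style hits tables. This is the only module that
converts between on-disk 1-based conventions and the internal 0-based
half-open coordinates.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import pysam

from .core import Annotation, DeletionCall, GeneModel, GenomicInterval, Genotype

logger = logging.getLogger(__name__)

__all__ = [
    "read_deletions_vcf",
    "read_gff3",
    "write_consensus_vcf",
    "write_loci_vcf",
    "write_deletion_vcf",
    "write_bed",
    "read_bed",
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "read_hits_tsv",
    "write_hits_tsv",
]

_GT_MAP = {
    (0, 0): Genotype.REF_REF,
    (0, 1): Genotype.REF_DEL,
    (1, 0): Genotype.REF_DEL,
    (1, 1): Genotype.DEL_DEL,
}


def _genotype_from_gt(gt) -> Optional[Genotype]:
    """Map a pysam GT tuple to a Genotype; None means reject the record."""
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    if any(a is None for a in gt):
        return Genotype.MISSING
    alleles = tuple(int(a) for a in gt)
    if any(a > 1 or a < 0 for a in alleles):
        return None  # allele index outside the biallelic model
    if len(alleles) == 1:  # haploid call, promote conservatively
        return Genotype.DEL_DEL if alleles[0] == 1 else Genotype.REF_REF
    return _GT_MAP.get(alleles[:2], None)


def read_deletions_vcf(
    path: str | os.PathLike,
    caller_id: str,
    counts: Optional[dict] = None,
) -> list[DeletionCall]:
    """Read deletion records from a VCF into :class:`DeletionCall` objects.

    Symbolic ``<DEL>`` records use ``[POS, END)`` (the 1-based POS is the
    padding base, so it equals the 0-based deleted start); explicit-allele
    records use the shared-padding convention with length
    ``len(REF) - len(ALT)``. Non-deletion records are counted and skipped;
    malformed or multi-allelic records are rejected with a warning tally.

    Parameters
    ----------
    path : path to a VCF 4.x file (plain text or bgzipped).
    caller_id : label recorded on every returned call.
    counts : optional dict that receives the tallies
        ``{"parsed", "skipped_non_del", "rejected"}``.
    """
    if not caller_id:
        raise ValueError("caller_id must be non-empty")
    tallies = {"parsed": 0, "skipped_non_del": 0, "rejected": 0}
    calls: list[DeletionCall] = []
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        record_no = 0
        try:
            for rec in vcf:
                record_no += 1
                parsed = _parse_deletion_record(rec, caller_id, tallies)
                calls.extend(parsed)
        except Exception as exc:
            if isinstance(exc, ValueError) and "cannot parse" in str(exc):
                raise
            raise ValueError(
                f"cannot parse VCF {path} at record {record_no + 1} "
                f"(header + {record_no + 1} data lines in): {exc}"
            ) from exc
    if counts is not None:
        counts.update(tallies)
    if tallies["skipped_non_del"] or tallies["rejected"]:
        logger.warning(
            "%s: %d deletion calls parsed, %d non-DEL records skipped, "
            "%d records rejected",
            path,
            tallies["parsed"],
            tallies["skipped_non_del"],
            tallies["rejected"],
        )
    return calls


def _raw_end(rec) -> Optional[int]:
    """The END value as printed in the record's INFO column, if any."""
    try:
        info = str(rec).split("\t")[7]
    except IndexError:
        return None
    for item in info.split(";"):
        if item.startswith("END="):
            try:
                return int(item[4:])
            except ValueError:
                return None
    return None


def _parse_deletion_record(rec, caller_id: str, tallies: dict) -> list[DeletionCall]:
    alts = rec.alts
    if alts is None or len(alts) == 0:
        tallies["skipped_non_del"] += 1
        return []
    if len(alts) > 1:
        logger.warning("multi-allelic record at %s:%d rejected", rec.chrom, rec.pos)
        tallies["rejected"] += 1
        return []
    alt = alts[0]
    svtype = rec.info.get("SVTYPE")
    svlen = rec.info.get("SVLEN")
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]

    if alt == "<DEL>" or (svtype == "DEL" and alt.startswith("<")):
        # symbolic: POS is the padding base; deleted span is [POS, END) 0-based
        start = rec.pos  # 1-based POS == 0-based deleted start
        # htslib folds INFO/END into rec.stop and, when SVLEN is also set,
        # resolves conflicts in SVLEN's favour; recover the printed END from
        # the record text so that END wins as the positional field
        end = _raw_end(rec)
        if end is None:
            default_stop = rec.start + len(rec.ref or "N")
            if rec.stop is not None and rec.stop != default_stop:
                end = rec.stop
        if svlen is not None:
            svlen_end = start + abs(int(svlen))
            if end is None:
                end = svlen_end
            elif end != svlen_end:
                logger.warning(
                    "END/SVLEN disagree at %s:%d (END=%d, SVLEN=%s); END wins",
                    rec.chrom, rec.pos, end, svlen,
                )
        if end is None or end <= start:
            logger.warning(
                "malformed symbolic DEL at %s:%d (END <= POS or missing)",
                rec.chrom, rec.pos,
            )
            tallies["rejected"] += 1
            return []
        interval = GenomicInterval(rec.chrom, start, end)
    elif alt.startswith("<") or svtype not in (None, "DEL"):
        tallies["skipped_non_del"] += 1
        return []
    else:
        ref = rec.ref or ""
        if len(ref) <= len(alt) or any(c not in "ACGTNacgtn" for c in ref + alt):
            tallies["skipped_non_del"] += 1
            return []
        # explicit deletion: the first len(ALT) bases are retained padding
        start = (rec.pos - 1) + len(alt)
        end = start + (len(ref) - len(alt))
        interval = GenomicInterval(rec.chrom, start, end)

    calls = []
    record_id = rec.id or "."
    qual = float(rec.qual) if rec.qual is not None else None
    if len(rec.samples) == 0:
        calls.append(
            DeletionCall(interval, "", caller_id, Genotype.MISSING, qual, record_id)
        )
        tallies["parsed"] += 1
        return calls
    for sample_name, sample in rec.samples.items():
        gt = sample.get("GT") if "GT" in sample else None
        genotype = _genotype_from_gt(gt)
        if genotype is None:
            logger.warning(
                "allele index > 1 at %s:%d, record rejected", rec.chrom, rec.pos
            )
            tallies["rejected"] += 1
            return []
        calls.append(
            DeletionCall(interval, sample_name, caller_id, genotype, qual, record_id)
        )
    tallies["parsed"] += 1
    return calls


# ---------------------------------------------------------------------------
# GFF3


def _merge_intervals(ivs: list[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Union-merge overlapping or touching intervals (one chrom)."""
    if not ivs:
        return ()
    ivs = sorted(ivs, key=lambda iv: iv.start)
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


def read_gff3(path: str | os.PathLike) -> Annotation:
    """Parse a GFF3 into a validated :class:`Annotation`.

    Gene and exon features are required; exon ``Parent`` attributes must
    resolve to a gene directly or through a transcript. Exons from multiple
    transcripts are union-merged per gene. GFF3 1-based inclusive coordinates
    are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_features = {f.id: f for f in db.features_of_type("gene")}
    exons_by_gene: dict[str, list[GenomicInterval]] = {g: [] for g in gene_features}
    for exon in db.features_of_type("exon"):
        gene_ids = set()
        for parent_id in exon.attributes.get("Parent", []):
            if parent_id in gene_features:
                gene_ids.add(parent_id)
                continue
            try:
                parent = db[parent_id]
            except gffutils.FeatureNotFoundError:
                raise ValueError(
                    f"orphan exon at {exon.seqid}:{exon.start}-{exon.end}: "
                    f"Parent {parent_id!r} not found"
                ) from None
            for grand in parent.attributes.get("Parent", []):
                if grand in gene_features:
                    gene_ids.add(grand)
        if not gene_ids:
            raise ValueError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} has no "
                f"resolvable gene parent"
            )
        for gid in gene_ids:
            exons_by_gene[gid].append(
                GenomicInterval(exon.seqid, exon.start - 1, exon.end)
            )

    genes = []
    for gid, feat in gene_features.items():
        attrs = feat.attributes
        biotype = (
            attrs.get("gene_biotype", attrs.get("biotype", ["protein_coding"]))
        )[0]
        name = attrs.get("Name", attrs.get("gene_name", [gid]))[0]
        span = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        exons = _merge_intervals(exons_by_gene[gid])
        for exon in exons:
            if exon.start < span.start or exon.end > span.end:
                raise ValueError(
                    f"exon [{exon.start}, {exon.end}) outside span of gene {gid}"
                )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(GeneModel(gid, name, biotype, span, strand, exons))
    return Annotation(genes)


def write_gff3(annotation: Annotation, path: str | os.PathLike) -> None:
    """Write an annotation as GFF3 (gene -> mRNA -> exon), 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in annotation:
        c = g.span.chrom
        attrs = f"ID={g.gene_id};Name={g.gene_name};gene_biotype={g.biotype}"
        lines.append(
            f"{c}\tdelscan\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        tx = f"{g.gene_id}.t1"
        lines.append(
            f"{c}\tdelscan\tmRNA\t{g.span.start + 1}\t{g.span.end}\t.\t{g.strand}\t.\t"
            f"ID={tx};Parent={g.gene_id}"
        )
        for i, exon in enumerate(g.exons, 1):
            lines.append(
                f"{c}\tdelscan\texon\t{exon.start + 1}\t{exon.end}\t.\t{g.strand}\t.\t"
                f"ID={tx}.exon{i};Parent={tx}"
            )
    _write_lines(path, lines)


# ---------------------------------------------------------------------------
# VCF writing

_VCF_INFO_HEADER = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers supporting this deletion">',
    '##INFO=<ID=RO,Number=1,Type=Float,Description="Reciprocal overlap between supporting calls">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _vcf_header(samples: Sequence[str], contigs: Iterable[str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2"]
    for chrom in contigs:
        lines.append(f"##contig=<ID={chrom}>")
    lines.extend(_VCF_INFO_HEADER)
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols.append("FORMAT")
        cols.extend(samples)
    lines.append("\t".join(cols))
    return lines


def _del_record_fields(interval: GenomicInterval, info_extra: str = "") -> list[str]:
    info = f"SVTYPE=DEL;END={interval.end};SVLEN=-{interval.length}"
    if info_extra:
        info += ";" + info_extra
    # POS prints the 0-based start directly: it is the 1-based padding base
    return [interval.chrom, str(interval.start), ".", "N", "<DEL>", ".", "PASS", info]


def write_deletion_vcf(
    calls: Sequence[DeletionCall], path: str | os.PathLike, sample_id: str
) -> None:
    """Write one sample's deletion calls as a single-sample symbolic VCF."""
    contigs = sorted({c.interval.chrom for c in calls})
    lines = _vcf_header([sample_id], contigs)
    ordered = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    for call in ordered:
        fields = _del_record_fields(call.interval)
        fields[2] = call.record_id
        if call.qual is not None:
            fields[5] = f"{call.qual:g}"
        fields.extend(["GT", call.genotype.value])
        lines.append("\t".join(fields))
    _write_lines(path, lines)


def write_consensus_vcf(calls, path: str | os.PathLike) -> None:
    """Write consensus deletions (one record per per-sample call).

    Every sample seen in *calls* gets a genotype column; samples without a
    call at a record carry ``./.``. INFO carries CALLERS and the matched
    reciprocal overlap RO.
    """
    samples = sorted({c.sample_id for c in calls})
    contigs = sorted({c.interval.chrom for c in calls})
    lines = _vcf_header(samples, contigs)
    ordered = sorted(
        calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample_id)
    )
    for call in ordered:
        extra = f"CALLERS={','.join(call.callers)};RO={call.matched_ro:.4f}"
        fields = _del_record_fields(call.interval, extra)
        fields.append("GT")
        for s in samples:
            fields.append(call.genotype.value if s == call.sample_id else "./.")
        lines.append("\t".join(fields))
    _write_lines(path, lines)


def write_loci_vcf(loci, samples: Sequence[str], path: str | os.PathLike) -> None:
    """Write cross-sample deletion loci as a multi-sample VCF."""
    contigs = sorted({l.representative.chrom for l in loci})
    lines = _vcf_header(list(samples), contigs)
    ordered = sorted(loci, key=lambda l: (l.representative.chrom, l.representative.start))
    for locus in ordered:
        fields = _del_record_fields(locus.representative)
        fields.append("GT")
        for s in samples:
            gt = locus.members.get(s, Genotype.REF_REF)
            fields.append(gt.value)
        lines.append("\t".join(fields))
    _write_lines(path, lines)


def _write_lines(path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as 3-column BED (0-based half-open, as stored)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | os.PathLike) -> dict[str, GeneSet]:
    """Read a GMT file into named gene sets; short lines are skipped."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                logger.warning("%s line %d: <3 fields, skipped", path, lineno)
                continue
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = GeneSet(name, desc, frozenset(members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# BLAST-style 12-column hits


def read_hits_tsv(path: str | os.PathLike):
    """Read a 12-column tabular alignment file into MarkerHit records.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.
    """
    from .markers import MarkerHit

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path} line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: non-numeric evalue {fields[10]!r}"
                ) from None
            hits.append(
                MarkerHit(
                    marker_id=fields[0],
                    subject=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=evalue,
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_hits_tsv(hits, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.marker_id, h.subject, h.percent_identity,
                        h.alignment_length, h.mismatches, h.gap_opens,
                        h.qstart, h.qend, h.sstart, h.send, h.evalue, h.bitscore,
                    ]
                )
                + "\n"
            )
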