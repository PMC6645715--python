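"""Readers and writers for the formats the pipeline consumes and emits.

Reads travel either as SAM/BAM (molecular tag in an auxiliary field,
default ``RX``; qualities in QUAL) via pysam, or as a plain TSV dialect
(read_id, chrom, pos, strand, tag, quals as comma-separated PHRED ints).
Gene models travel as GTF (attribute keys ``gene_id`` and ``biotype``) or
BED6 plus a biotype column; counts as a genes x samples TSV with a sidecar
sample table mapping sample -> state/replicate/mapped_total.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .counting import CountMatrix, GeneModel
from .dedup import DedupResult, TaggedRead

__all__ = [
    "write_reads_tsv",
    "read_reads_tsv",
    "write_reads_sam",
    "read_reads_sam",
    "write_flagged_sam",
    "write_gtf",
    "read_gtf",
    "write_bed",
    "read_bed",
    "write_counts",
    "read_counts",
    "write_table",
]

READS_TSV_COLUMNS = ["read_id", "chrom", "pos", "strand", "tag", "quals", "mean_phred"]


def write_reads_tsv(reads: Sequence[TaggedRead], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(READS_TSV_COLUMNS)
        for r in reads:
            writer.writerow(
                [
                    r.read_id,
                    r.chrom,
                    r.pos,
                    r.strand,
                    r.tag,
                    ",".join(map(str, r.quals)),
                    f"{r.mean_phred:.6f}",
                ]
            )


def read_reads_tsv(path) -> List[TaggedRead]:
    reads: List[TaggedRead] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(READS_TSV_COLUMNS[:-1]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                reads.append(
                    TaggedRead(
                        read_id=row["read_id"],
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        strand=row["strand"],
                        tag=row["tag"],
                        quals=tuple(int(q) for q in row["quals"].split(",")),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return reads


def _sam_header(chrom_lengths: Dict[str, int]) -> Dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }


def write_reads_sam(
    reads: Sequence[TaggedRead],
    path,
    chrom_lengths: Dict[str, int],
    tag_field: str = "RX",
    duplicate_flags: Optional[Dict[str, bool]] = None,
) -> None:
    """Write reads as SAM; sets the 0x400 duplicate FLAG bit when given."""
    path = str(path)
    mode = "wb" if path.endswith(".bam") else "w"
    header = pysam.AlignmentHeader.from_dict(_sam_header(chrom_lengths))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.reference_id = list(chrom_lengths).index(r.chrom)
            seg.reference_start = r.pos
            seg.mapping_quality = 60
            seg.cigarstring = f"{len(r.quals)}M"
            seg.query_sequence = "N" * len(r.quals)
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            flag = 16 if r.strand == "-" else 0
            if duplicate_flags and duplicate_flags.get(r.read_id):
                flag |= 0x400
            seg.flag = flag
            seg.set_tag(tag_field, r.tag)
            out.write(seg)


def read_reads_sam(path, tag_field: str = "RX") -> List[TaggedRead]:
    reads: List[TaggedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for seg in handle.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            if not seg.has_tag(tag_field):
                raise ValueError(f"{path}: read {seg.query_name} lacks {tag_field} tag")
            quals = seg.query_qualities
            if quals is None:
                raise ValueError(f"{path}: read {seg.query_name} has no qualities")
            reads.append(
                TaggedRead(
                    read_id=seg.query_name,
                    chrom=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    tag=str(seg.get_tag(tag_field)),
                    quals=tuple(int(q) for q in quals),
                )
            )
    return reads


def write_flagged_sam(
    reads: Sequence[TaggedRead],
    result: DedupResult,
    path,
    chrom_lengths: Dict[str, int],
    tag_field: str = "RX",
) -> None:
    write_reads_sam(
        reads, path, chrom_lengths, tag_field=tag_field, duplicate_flags=result.duplicate
    )


def write_gtf(models: Sequence[GeneModel], path, source: str = "temposeq") -> None:
    with open(path, "w") as handle:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; biotype "{m.biotype}";'
                handle.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def _parse_gtf_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> List[GeneModel]:
    """Collect exon features into per-gene models (1-based GTF -> 0-based)."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attr_text = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_text)
            if "gene_id" not in attrs:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            exons.setdefault(gid, []).append((int(start) - 1, int(end)))
            meta.setdefault(gid, (chrom, strand, attrs.get("biotype", "protein_coding")))
    return [
        GeneModel(gene_id=gid, chrom=meta[gid][0], strand=meta[gid][1],
                  exons=tuple(exons[gid]), biotype=meta[gid][2])
        for gid in exons
    ]


def write_bed(models: Sequence[GeneModel], path) -> None:
    """BED6 plus a 7th biotype column, one row per exon."""
    with open(path, "w") as handle:
        for m in models:
            for s, e in m.exons:
                handle.write(f"{m.chrom}\t{s}\t{e}\t{m.gene_id}\t0\t{m.strand}\t{m.biotype}\n")


def read_bed(path) -> List[GeneModel]:
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 BED columns")
            chrom, start, end, gid, _, strand, biotype = fields[:7]
            exons.setdefault(gid, []).append((int(start), int(end)))
            meta.setdefault(gid, (chrom, strand, biotype))
    return [
        GeneModel(gene_id=gid, chrom=meta[gid][0], strand=meta[gid][1],
                  exons=tuple(exons[gid]), biotype=meta[gid][2])
        for gid in exons
    ]


def write_counts(matrix: CountMatrix, counts_path, samples_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    table = matrix.samples.loc[matrix.counts.columns].copy()
    table["mapped_total"] = matrix.mapped_totals
    table.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    totals = None
    if "mapped_total" in samples.columns:
        totals = samples["mapped_total"].astype(float)
    return CountMatrix(counts=counts, samples=samples, mapped_totals=totals)


def write_table(frame: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)
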