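"""Readers and writers for the plain-text formats the pipeline speaks.

Tags travel as BED6 (one record per deduplicable 5'-end tag), genomes as
two-column chrom-sizes TSV, gene models as GFF3, count matrices and sample
sheets as TSV, truth tables as JSON, and called regions as BED6 with the
comparison-1 p-value encoded in the score column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .windowing import AlignedTag, CountMatrix, GenomeLayout

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed_tags",
    "write_bed_tags",
    "read_sam_tags",
    "read_gene_models",
    "write_gff3",
    "read_count_matrix",
    "write_count_matrix",
    "read_bed_intervals",
    "write_gain_regions_bed",
    "write_truth_json",
]


def read_chrom_sizes(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.chroms:
            fh.write(f"{chrom}\t{length}\n")


def read_bed_tags(path) -> list[AlignedTag]:
    """BED6 records to tags: 5' end = start for +, end - 1 for -.

    The score column carries the mapping quality.
    """
    tags = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _name, score, strand = line.rstrip("\n").split("\t")[:6]
            pos5 = int(start) if strand == "+" else int(end) - 1
            tags.append(AlignedTag(chrom, pos5, strand, mapq=int(float(score))))
    return tags


def write_bed_tags(tags: Sequence[AlignedTag], path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            start = t.pos5 if t.strand == "+" else t.pos5  # 1-bp record at the 5' end
            fh.write(f"{t.chrom}\t{start}\t{start + 1}\ttag{i}\t{t.mapq}\t{t.strand}\n")


def read_sam_tags(path, mapq_min: int = 0) -> list[AlignedTag]:
    """Coordinate alignments (SAM/BAM) reduced to 5'-end tags via pysam."""
    import pysam

    tags = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            strand = "-" if rec.is_reverse else "+"
            pos5 = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            tags.append(AlignedTag(rec.reference_name, pos5, strand, rec.mapping_quality))
    return tags


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Gene models to GFF3 (gene / exon / UTR features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsixma\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsixma\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (s, e) in enumerate(g.utrs, 1):
                fh.write(
                    f"{g.chrom}\tsixma\tUTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.utr{i};Parent={g.gene_id}\n"
                )


def read_gene_models(path) -> list[GeneModel]:
    """GFF3 to gene models via gffutils; genes keyed by their ID attribute."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    seen = set()
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r}")
        seen.add(gid)
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(gene, featuretype="exon"))
        )
        utrs = tuple(
            sorted((f.start - 1, f.end) for f in db.children(gene, featuretype="UTR"))
        )
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                utrs=utrs,
            )
        )
    return models


def write_count_matrix(cm: CountMatrix, counts_path, sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(sheet_path, sep="\t")


def read_count_matrix(counts_path, sheet_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(sheet_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, samples=samples)


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """BED3+ records as (chrom, start, end) tuples (peaks, regions)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_gain_regions_bed(
    region_ids: Sequence[str], path, pvalues: dict[str, float] | None = None
) -> None:
    """Gain regions as BED6; score = -10 log10(p) of comparison 1, capped at 1000."""
    with open(path, "w") as fh:
        for rid in region_ids:
            chrom, span = rid.rsplit(":", 1)
            start, end = span.split("-")
            score = 0
            if pvalues and rid in pvalues:
                p = max(pvalues[rid], 1e-100)
                score = min(int(round(-10 * np.log10(p))), 1000)
            fh.write(f"{chrom}\t{start}\t{end}\t{rid}\t{score}\t.\n")


def write_truth_json(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
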