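"""Genomic feature annotation, TSS profiles, and IUPAC motif scanning.

Regions are classified into one of six categories by their midpoint with
the precedence

    proximal_promoter > distal_promoter > utr > exon > intron > intergenic

Promoter windows are measured upstream of the TSS on the coding strand:
proximal covers TSS-relative -1000..-1, distal -10000..-1001 (both
configurable). TSS-relative coordinates count upstream bases from -1
(adjacent to the TSS) with no position 0; the TSS base itself is +1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .windowing import AlignedTag, Window

__all__ = [
    "FEATURE_LABELS",
    "GeneModel",
    "MotifHit",
    "annotate_region",
    "summarize_annotation",
    "scan_motif",
    "tss_profile",
]

FEATURE_LABELS = (
    "proximal_promoter",
    "distal_promoter",
    "utr",
    "exon",
    "intron",
    "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS, exon and UTR structure.

    ``start``/``end`` are the 0-based half-open genomic span; ``exons`` and
    ``utrs`` are sorted non-overlapping half-open intervals inside it.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        for s, e in self.exons + self.utrs:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"interval [{s}, {e}) outside gene span")

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    def tss_relative(self, pos: int) -> int:
        """TSS-relative coordinate of an absolute position (-1 adjacent)."""
        d = pos - self.tss if self.strand == "+" else self.tss - pos
        return d if d < 0 else d + 1


def _midpoint(region) -> tuple[str, int]:
    if isinstance(region, Window):
        return region.chrom, region.midpoint
    if isinstance(region, str):  # "chrom:start-end" window id
        chrom, span = region.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        return chrom, (start + end) // 2
    chrom, start, end = region
    return chrom, (int(start) + int(end)) // 2


def _gene_label(gene: GeneModel, m: int, proximal_bp: int, distal_bp: int) -> str | None:
    """Feature label the midpoint gets from this one gene, or None."""
    rel = gene.tss_relative(m)
    if -proximal_bp <= rel <= -1:
        return "proximal_promoter"
    if -distal_bp <= rel < -proximal_bp:
        return "distal_promoter"
    if gene.start <= m < gene.end:
        for s, e in gene.utrs:
            if s <= m < e:
                return "utr"
        for s, e in gene.exons:
            if s <= m < e:
                return "exon"
        return "intron"
    return None


def annotate_region(
    region,
    models: Sequence[GeneModel],
    proximal_bp: int = 1000,
    distal_bp: int = 10000,
) -> str:
    """Classify one region (a :class:`Window` or ``(chrom, start, end)``).

    When several genes cover the midpoint the highest-precedence label
    wins; among genes offering that label the nearest TSS is used, ties
    broken by lexicographic gene id. Midpoints on chromosomes with no
    annotated gene are intergenic; an unknown chromosome must be caught by
    the caller (the model list carries no genome bounds).
    """
    chrom, m = _midpoint(region)
    best: tuple[int, int, str] | None = None  # (precedence, distance, gene_id)
    label = "intergenic"
    for g in models:
        if g.chrom != chrom:
            continue
        lab = _gene_label(g, m, proximal_bp, distal_bp)
        if lab is None:
            continue
        key = (FEATURE_LABELS.index(lab), abs(m - g.tss), g.gene_id)
        if best is None or key < best:
            best = key
            label = lab
    return label


def summarize_annotation(
    regions: Sequence,
    models: Sequence[GeneModel],
    proximal_bp: int = 1000,
    distal_bp: int = 10000,
) -> pd.DataFrame:
    """Counts and fractions per feature label over a region set.

    Fractions sum to 1 within 1e-9. Raises on an empty region set.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("empty region set")
    labels = [annotate_region(r, models, proximal_bp, distal_bp) for r in regions]
    counts = pd.Series(labels).value_counts().reindex(FEATURE_LABELS, fill_value=0)
    return pd.DataFrame(
        {"count": counts.astype(int), "fraction": counts / counts.sum()}
    )


@dataclass(frozen=True)
class MotifHit:
    """An exact IUPAC motif match with absolute and TSS-relative spans.

    ``start``/``end`` are 0-based half-open within the scanned sequence;
    ``rel_start``/``rel_end`` are inclusive TSS-relative coordinates in
    gene orientation (negative upstream, -1 adjacent to the TSS).
    """

    motif: str
    strand: str
    start: int
    end: int
    rel_start: int
    rel_end: int
    matched: str


_COMPLEMENT = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for c in motif.upper():
        if c not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC code {c!r} in motif {motif!r}")
        bases = ambiguous_dna_values[c]
        if c == "N":
            bases += "N"  # an unknown genomic base satisfies an any-base slot
        parts.append(c if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motif(
    sequence: str,
    motif: str,
    tss_pos: int,
    strand: str = "+",
) -> list[MotifHit]:
    """All exact IUPAC matches of ``motif`` on the given strand.

    ``sequence`` is the forward genomic sequence; ``tss_pos`` the 0-based
    index of the TSS base within it. For ``strand='-'`` the reverse
    complement of the motif is matched on the forward sequence and
    coordinates are reported in gene (minus-strand) orientation.
    Overlapping matches are all reported.
    """
    seq = sequence.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    query = motif.upper() if strand == "+" else motif.upper().translate(_COMPLEMENT)[::-1]
    pat = _iupac_regex(query)

    def rel(p: int) -> int:
        d = p - tss_pos if strand == "+" else tss_pos - p
        return d if d < 0 else d + 1

    hits = []
    for m in pat.finditer(seq):
        i = m.start()
        j = i + len(motif)
        if strand == "+":
            r1, r2 = rel(i), rel(j - 1)
        else:
            r1, r2 = rel(j - 1), rel(i)
        hits.append(
            MotifHit(
                motif=motif.upper(),
                strand=strand,
                start=i,
                end=j,
                rel_start=min(r1, r2),
                rel_end=max(r1, r2),
                matched=m.group(1),
            )
        )
    return hits


def tss_profile(
    tags: Sequence[AlignedTag],
    models: Sequence[GeneModel],
    flank_bp: int = 2000,
    bin_bp: int = 100,
) -> pd.DataFrame:
    """Average per-bp tag density in strand-oriented bins around the TSS.

    Bins tile TSS-relative offsets ``-flank_bp .. +flank_bp`` (upstream
    negative); densities are tags per bp per gene. ``flank_bp`` must be a
    multiple of ``bin_bp``.
    """
    if not models:
        raise ValueError("no gene models")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    edges = np.arange(-flank_bp, flank_bp + bin_bp, bin_bp)
    hist = np.zeros(n_bins, dtype=float)

    by_chrom: dict[str, list[int]] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append(t.pos5)
    pos_arrays = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}

    for g in models:
        pos = pos_arrays.get(g.chrom)
        if pos is None:
            continue
        if g.strand == "+":
            lo, hi, side = g.tss - flank_bp, g.tss + flank_bp, "left"
        else:  # offset -flank maps to pos tss+flank; keep bounds half-open in offset space
            lo, hi, side = g.tss - flank_bp, g.tss + flank_bp, "right"
        window = pos[np.searchsorted(pos, lo, side=side): np.searchsorted(pos, hi, side=side)]
        d = window - g.tss if g.strand == "+" else g.tss - window
        d = d[(d >= -flank_bp) & (d < flank_bp)]
        hist += np.histogram(d, bins=edges)[0]

    density = hist / (len(models) * bin_bp)
    return pd.DataFrame(
        {
            "offset_start": edges[:-1],
            "offset_end": edges[1:],
            "density": density,
        }
    )
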