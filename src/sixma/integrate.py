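"""Gene-set integration of gain-of-6mA regions, expression, and peaks.

Implements the gene-class logic downstream of region calling: genes
co-regulated by hypoxia and the methyltransferase (up under hypoxia, down
under knockdown, in every cell line), genes carrying gain-of-6mA regions,
and the split of those genes by direct transcription-factor peak binding
(e.g. HIF-1a ChIP peaks) versus 6mA regulation without direct binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

from .annotate import GeneModel

__all__ = [
    "GeneSet",
    "RegionGeneMap",
    "assign_regions_to_genes",
    "intersect_sets",
    "classify_by_peak_overlap",
    "build_coregulated_gene_list",
]


@dataclass(frozen=True)
class GeneSet:
    label: str
    ids: frozenset[str]

    def __init__(self, label: str, ids):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "ids", frozenset(str(i) for i in ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gid) -> bool:
        return gid in self.ids


@dataclass
class RegionGeneMap:
    """Region -> gene assignments with the rule that produced each link.

    ``assignments`` maps region id to a list of ``(gene_id, rule)`` pairs,
    rule being ``"body"`` or ``"promoter"``; multi-gene assignments are
    retained. ``unmapped`` lists regions overlapping no gene.
    """

    assignments: dict[str, list[tuple[str, str]]]
    unmapped: list[str]

    def genes(self) -> set[str]:
        return {g for pairs in self.assignments.values() for g, _ in pairs}


def _parse_region(region) -> tuple[str, int, int, str]:
    if isinstance(region, str):
        chrom, span = region.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        return chrom, start, end, region
    chrom, start, end = region[:3]
    return str(chrom), int(start), int(end), f"{chrom}:{start}-{end}"


def _gene_footprint(g: GeneModel, promoter_bp: int) -> tuple[int, int, int, int]:
    """(body_start, body_end, promoter_start, promoter_end), half-open."""
    if g.strand == "+":
        return g.start, g.end, max(g.start - promoter_bp, 0), g.start
    return g.start, g.end, g.end, g.end + promoter_bp


def assign_regions_to_genes(
    regions: Sequence,
    models: Sequence[GeneModel],
    promoter_bp: int = 10_000,
) -> RegionGeneMap:
    """Assign each region to every gene it overlaps (body or promoter).

    A region is linked to a gene when it overlaps the gene body or the
    strand-aware upstream promoter window of ``promoter_bp``; body overlap
    takes the ``"body"`` rule tag even if the promoter also overlaps.
    """
    assignments: dict[str, list[tuple[str, str]]] = {}
    unmapped: list[str] = []
    feet = [(g, _gene_footprint(g, promoter_bp)) for g in models]
    for region in regions:
        chrom, start, end, rid = _parse_region(region)
        pairs: list[tuple[str, str]] = []
        for g, (bs, be, ps, pe) in feet:
            if g.chrom != chrom:
                continue
            if start < be and end > bs:
                pairs.append((g.gene_id, "body"))
            elif start < pe and end > ps:
                pairs.append((g.gene_id, "promoter"))
        if pairs:
            assignments[rid] = sorted(pairs)
        else:
            unmapped.append(rid)
    return RegionGeneMap(assignments=assignments, unmapped=unmapped)


def intersect_sets(sets: Sequence[GeneSet]) -> tuple[GeneSet, dict[tuple[bool, ...], int]]:
    """Intersection of gene sets plus all Venn cell counts.

    Venn cells are keyed by the membership pattern over the input sets in
    order (the all-False cell is omitted); cell counts sum to the size of
    the union. Commutative and associative in the returned intersection.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one gene set")
    inter = frozenset.intersection(*(s.ids for s in sets))
    union = frozenset.union(*(s.ids for s in sets))
    venn: dict[tuple[bool, ...], int] = {
        pattern: 0 for pattern in product([False, True], repeat=len(sets))
        if any(pattern)
    }
    for gid in union:
        pattern = tuple(gid in s.ids for s in sets)
        venn[pattern] += 1
    label = " & ".join(s.label for s in sets)
    return GeneSet(label, inter), venn


def classify_by_peak_overlap(
    genes: GeneSet,
    peaks: Sequence,
    models: Sequence[GeneModel],
    promoter_bp: int = 10_000,
) -> tuple[GeneSet, GeneSet]:
    """Partition genes by whether any peak overlaps their body or promoter.

    Returns ``(bound, unbound)``; the two are disjoint and their union is
    the input set. Genes absent from the models cannot be bound.
    """
    by_id = {g.gene_id: g for g in models}
    parsed = [_parse_region(p)[:3] for p in peaks]
    bound = set()
    for gid in genes.ids:
        g = by_id.get(gid)
        if g is None:
            continue
        bs, be, ps, pe = _gene_footprint(g, promoter_bp)
        lo, hi = min(bs, ps), max(be, pe)
        if any(c == g.chrom and s < hi and e > lo for c, s, e in parsed):
            bound.add(gid)
    return (
        GeneSet(f"{genes.label} (bound)", bound),
        GeneSet(f"{genes.label} (unbound)", genes.ids - bound),
    )


def build_coregulated_gene_list(
    de_tables: Mapping[str, Mapping[str, pd.DataFrame]],
    direction_spec: Mapping[str, str] = None,
) -> GeneSet:
    """Genes co-regulated by hypoxia and the methyltransferase.

    ``de_tables[cell_line][contrast]`` are tables from
    :func:`sixma.nbstat.call_de` (indexed by gene, with a ``flag``
    column). The default direction spec requires ``up`` in
    ``hypoxia_vs_normoxia`` and ``down`` in ``kd_vs_ctrl``; a gene must
    satisfy every direction in every cell line.
    """
    if direction_spec is None:
        direction_spec = {"hypoxia_vs_normoxia": "up", "kd_vs_ctrl": "down"}
    result: frozenset[str] | None = None
    for line, contrasts in de_tables.items():
        for contrast, direction in direction_spec.items():
            if contrast not in contrasts:
                raise ValueError(
                    f"cell line {line!r} has no contrast {contrast!r}"
                )
            tab = contrasts[contrast]
            ids = frozenset(tab.index[tab["flag"] == direction].astype(str))
            result = ids if result is None else (result & ids)
    if result is None:
        raise ValueError("no differential-expression tables given")
    return GeneSet("coregulated", result)
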