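"""Feature classification, motif scanning and TSS profiles."""

import numpy as np
import pytest

from sixma.annotate import (
    FEATURE_LABELS,
    GeneModel,
    annotate_region,
    scan_motif,
    summarize_annotation,
    tss_profile,
)
from sixma.windowing import AlignedTag


def plus_gene(gene_id="g1", start=20_000, end=26_000):
    return GeneModel(
        gene_id=gene_id,
        chrom="chr1",
        strand="+",
        start=start,
        end=end,
        exons=((start, start + 1000), (end - 1500, end)),
        utrs=((start, start + 200),),
    )


def mirror(gene: GeneModel, chrom_len: int) -> GeneModel:
    """Reflect a gene through the chromosome midpoint, flipping strand."""
    flip = lambda s, e: (chrom_len - e, chrom_len - s)
    return GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand="-" if gene.strand == "+" else "+",
        start=chrom_len - gene.end,
        end=chrom_len - gene.start,
        exons=tuple(sorted(flip(s, e) for s, e in gene.exons)),
        utrs=tuple(sorted(flip(s, e) for s, e in gene.utrs)),
    )


def oracle_label(chrom, midpoint, models, proximal_bp=1000, distal_bp=10_000):
    """Independent per-region reimplementation of the classification rule."""
    candidates = []
    for g in models:
        if g.chrom != chrom:
            continue
        tss = g.start if g.strand == "+" else g.end - 1
        d = midpoint - tss if g.strand == "+" else tss - midpoint
        rel = d if d < 0 else d + 1
        lab = None
        if -proximal_bp <= rel <= -1:
            lab = "proximal_promoter"
        elif -distal_bp <= rel < -proximal_bp:
            lab = "distal_promoter"
        elif g.start <= midpoint < g.end:
            if any(s <= midpoint < e for s, e in g.utrs):
                lab = "utr"
            elif any(s <= midpoint < e for s, e in g.exons):
                lab = "exon"
            else:
                lab = "intron"
        if lab is not None:
            candidates.append((FEATURE_LABELS.index(lab), abs(midpoint - tss), g.gene_id, lab))
    if not candidates:
        return "intergenic"
    return min(candidates)[3]


class TestAnnotateRegion:
    def test_proximal_promoter(self):
        g = plus_gene()
        region = ("chr1", 19_400, 19_600)  # midpoint 500 bp upstream of TSS
        assert annotate_region(region, [g]) == "proximal_promoter"

    def test_exon_precedence_inside_body(self):
        g = plus_gene()
        region = ("chr1", 25_000, 25_200)  # inside the 3' exon, past any promoter
        assert annotate_region(region, [g]) == "exon"

    def test_far_region_is_intergenic(self):
        g = plus_gene()
        assert annotate_region(("chr1", 70_000, 76_000), [g]) == "intergenic"

    def test_utr_beats_exon(self):
        g = plus_gene()
        region = ("chr1", 20_050, 20_250)  # midpoint in the 5' UTR
        assert annotate_region(region, [g]) == "utr"

    def test_minus_strand_promoter_is_downstream_in_genome(self):
        g = GeneModel("gm", "chr1", "-", 10_000, 16_000)
        region = ("chr1", 16_200, 16_800)  # 500 bp past the gene end = upstream of - TSS
        assert annotate_region(region, [g]) == "proximal_promoter"


class TestSummarizeAnnotation:
    def test_degenerate_all_intergenic(self):
        g = plus_gene()
        regions = [("chr1", 100_000 + i * 3000, 103_000 + i * 3000) for i in range(10)]
        summary = summarize_annotation(regions, [g])
        assert summary.loc["intergenic", "fraction"] == 1.0
        assert summary["count"].sum() == 10

    def test_fractions_normalize(self, small_world):
        cfg, layout, models, counts, truth = small_world
        rng = np.random.default_rng(0)
        starts = rng.integers(0, layout.total_bp - 3000, size=300)
        regions = [("chr1", int(s), int(s) + 3000) for s in starts]
        summary = summarize_annotation(regions, models)
        assert summary["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_annotation([], [plus_gene()])

    def test_oracle_equivalence_random_regions(self, small_world):
        cfg, layout, models, counts, truth = small_world
        rng = np.random.default_rng(7)
        for _ in range(300):
            s = int(rng.integers(0, 597_000))
            region = ("chr1", s, s + 3000)
            assert annotate_region(region, models) == oracle_label("chr1", s + 1500, models)

    def test_strand_mirror_symmetry(self, small_world):
        cfg, layout, models, counts, truth = small_world
        L = layout.lengths["chr1"]
        mirrored = [mirror(g, L) for g in models]
        rng = np.random.default_rng(11)
        for _ in range(150):
            s = int(rng.integers(0, L - 3000))
            lab = annotate_region(("chr1", s, s + 3000), models)
            lab_m = annotate_region(("chr1", L - s - 3000, L - s), mirrored)
            assert lab == lab_m


class TestScanMotif:
    def test_planted_hre_at_stated_offset(self):
        # TSS at index 300; plant ACGTG covering TSS-relative -147..-143
        tss = 300
        seq = ["T"] * 600
        for k, base in enumerate("ACGTG"):
            seq[tss - 147 + k] = base
        hits = scan_motif("".join(seq), "ACGTG", tss_pos=tss)
        assert len(hits) == 1
        assert (hits[0].rel_start, hits[0].rel_end) == (-147, -143)

    def test_no_match_returns_empty(self):
        assert scan_motif("TTTTTTTT", "ACGTG", tss_pos=4) == []

    def test_iupac_expansion(self):
        hits = scan_motif("AACGTGAGCGTGA", "RCGTG", tss_pos=13)
        assert {h.matched for h in hits} == {"ACGTG", "GCGTG"}

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", "ACQT", tss_pos=2)

    def test_minus_strand_reports_gene_orientation(self):
        # ACGTG on the minus strand = CACGT on the forward strand
        seq = "TTTTTCACGTTTTTTTTTTT"
        tss = 2
        hits = scan_motif(seq, "ACGTG", tss_pos=tss, strand="-")
        assert len(hits) == 1
        fwd = scan_motif(seq[::-1].translate(str.maketrans("ACGT", "TGCA")), "ACGTG",
                         tss_pos=len(seq) - 1 - tss)
        assert (hits[0].rel_start, hits[0].rel_end) == (fwd[0].rel_start, fwd[0].rel_end)

    def test_overlapping_matches_all_reported(self):
        hits = scan_motif("AAAA", "AA", tss_pos=0)
        assert len(hits) == 3


class TestTssProfile:
    def _genes(self, n=40, spacing=10_000):
        return [
            GeneModel(f"g{i}", "chr1", "+" if i % 2 else "-",
                      5000 + i * spacing, 9000 + i * spacing)
            for i in range(n)
        ]

    def test_uniform_tags_give_flat_profile(self):
        rng = np.random.default_rng(0)
        genes = self._genes()
        tags = [AlignedTag("chr1", int(p), "+") for p in rng.integers(0, 410_000, 200_000)]
        prof = tss_profile(tags, genes, flank_bp=2000, bin_bp=500)
        d = prof["density"].to_numpy()
        assert d.std() / d.mean() < 0.1

    def test_planted_central_peak(self):
        genes = self._genes()
        tags = []
        for g in genes:
            tss = g.start if g.strand == "+" else g.end - 1
            tags += [AlignedTag("chr1", tss + off, "+") for off in range(-100, 100)]
        prof = tss_profile(tags, genes, flank_bp=2000, bin_bp=200)
        center = prof[(prof.offset_start >= -200) & (prof.offset_end <= 200)]["density"]
        outer = prof[(prof.offset_start < -400) | (prof.offset_start >= 400)]["density"]
        assert center.min() > 10 * max(outer.max(), 1e-9)

    def test_reflected_world_gives_identical_profile(self):
        # reflecting genes and tags through the chromosome midpoint flips
        # every strand; strand-aware offsets are invariant, so the profile
        # must be exactly unchanged
        L = 410_000
        genes = self._genes()
        rng = np.random.default_rng(3)
        pos = rng.integers(0, L, 50_000)
        tags = [AlignedTag("chr1", int(p), "+") for p in pos]
        tags_m = [AlignedTag("chr1", int(L - 1 - p), "+") for p in pos]
        genes_m = [mirror(g, L) for g in genes]
        a = tss_profile(tags, genes, flank_bp=1000, bin_bp=100)["density"].to_numpy()
        b = tss_profile(tags_m, genes_m, flank_bp=1000, bin_bp=100)["density"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_requires_genes_and_aligned_binning(self):
        with pytest.raises(ValueError):
            tss_profile([], [], flank_bp=1000, bin_bp=100)
        with pytest.raises(ValueError):
            tss_profile([], self._genes(2), flank_bp=1000, bin_bp=300)
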