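"""From differential expression to co-regulated, 6mA-linked gene classes.

Calls differential expression per cell line with the NB exact test
(fold > 1.3 and p < 0.05), intersects 'up under hypoxia' with 'down under
knockdown' across both lines, links genes to called gain-of-6mA regions,
and splits them by direct peak binding.
"""

from sixma import gaincall, integrate, nbstat, synthio

cfg = synthio.SimConfig(seed=1)
layout, models = synthio.simulate_genome(cfg)
counts, truth = synthio.simulate_counts(cfg, layout)
mats, truth2 = synthio.simulate_expression(cfg, models, truth)

de_tables = {}
for line, cm in mats.items():
    de_tables[line] = {}
    for contrast, (a, b) in {
        "hypoxia_vs_normoxia": ("normoxia", "hypoxia"),
        "kd_vs_ctrl": ("hypoxia_ctrl", "hypoxia_kd"),
    }.items():
        keep = [s for s in cm.sample_ids if cm.samples.loc[s, "condition"] in (a, b)]
        groups = {s: cm.samples.loc[s, "condition"] for s in keep}
        de_tables[line][contrast] = nbstat.call_de(cm.subset(keep), groups, (a, b))

coreg = integrate.build_coregulated_gene_list(de_tables)
planted = set(truth2.genes.index[truth2.genes["is_de"]])
print(f"co-regulated genes (up in hypoxia AND down under knockdown, both lines): "
      f"{len(coreg)}; {len(coreg.ids & planted)} of {len(planted)} planted recovered")

# link genes to called gain regions, then split by synthetic TF peaks
specs = gaincall.comparisons_from_sheet(counts)
results = [gaincall.run_comparison(counts, s) for s in specs]
wga = gaincall.wga_positive_windows(
    counts, counts.select_samples("hypoxia", "signal"), counts.select_samples(track="wga")
)
regions = gaincall.call_gain_regions(results, wga)
rmap = integrate.assign_regions_to_genes(regions.regions, models)
with_region = integrate.GeneSet("with gain-of-6mA region", coreg.ids & rmap.genes())
print(f"co-regulated genes carrying a gain-of-6mA region: {len(with_region)}")

peaks = [(g.chrom, max(g.start - 500, 0), g.start + 500)
         for g in models[::7]]  # synthetic TF peak set at every 7th promoter
bound, unbound = integrate.classify_by_peak_overlap(with_region, peaks, models)
print(f"of these, {len(bound)} have a direct peak, {len(unbound)} are "
      f"6mA-linked without direct binding")
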