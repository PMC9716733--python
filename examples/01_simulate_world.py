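"""Generate a synthetic 6mA ChIP-exo world and inspect its ground truth.

Builds the default toy genome (two 7.5 Mb chromosomes, 5000 3-kb windows),
simulates NB window counts for normoxia / hypoxia / knockdown / control
conditions across signal, input and WGA tracks, and prints what was
planted. Every number is reproducible from the seed.
"""

from sixma import synthio

cfg = synthio.SimConfig(seed=1)
layout, models = synthio.simulate_genome(cfg)
counts, truth = synthio.simulate_counts(cfg, layout)

print(f"genome: {layout.names} ({layout.total_bp / 1e6:.1f} Mb), {len(models)} genes")
print(f"count matrix: {counts.counts.shape[0]} windows x {counts.counts.shape[1]} samples")
print(counts.samples.groupby(['condition', 'track']).size().to_string())
print(f"planted: {len(truth.gain_ids)} gain windows (fold {cfg.gain_effect}), "
      f"{len(truth.artifact_ids)} WGA artifacts")
# The gain appears only in hypoxic signal tracks and reverts under knockdown;
# the artifact inflates WGA (and, less, hypoxic signal) without being real 6mA.
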