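import pytest

from sixma import gaincall, synthio


@pytest.fixture(scope="session")
def small_world():
    """A 200-window world with genes, counts and truth (fast, seeded)."""
    cfg = synthio.SimConfig(n_chroms=1, chrom_length=600_000, seed=101)
    layout, models = synthio.simulate_genome(cfg)
    counts, truth = synthio.simulate_counts(cfg, layout)
    return cfg, layout, models, counts, truth


@pytest.fixture(scope="session")
def default_world():
    """The full default world: 5000 windows, planted gains and artifacts."""
    cfg = synthio.SimConfig(seed=1)
    layout, models = synthio.simulate_genome(cfg)
    counts, truth = synthio.simulate_counts(cfg, layout)
    return cfg, layout, models, counts, truth


@pytest.fixture(scope="session")
def default_gain_call(default_world):
    """Full pipeline run on the default world (shared across tests)."""
    cfg, layout, models, counts, truth = default_world
    specs = gaincall.comparisons_from_sheet(counts)
    results = [gaincall.run_comparison(counts, s) for s in specs]
    wga = gaincall.wga_positive_windows(
        counts,
        counts.select_samples("hypoxia", "signal"),
        counts.select_samples(track="wga"),
    )
    regions = gaincall.call_gain_regions(results, wga)
    return specs, results, wga, regions
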