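"""Synthetic data with known ground truth for the 6mA pipeline.

The generator emulates the *structure* of a hypoxia 6mA ChIP-exo study —
not the sequence content of any real genome. It produces:

* a toy genome layout and gene models (GFF3-writable),
* NB-distributed window counts for four conditions (normoxia, hypoxia,
  hypoxia + methyltransferase knockdown, hypoxia + control knockdown)
  across signal, input and WGA tracks, with planted gain-of-6mA windows
  and planted WGA amplification artifacts,
* gene-level expression count matrices for two cell lines, with
  differentially expressed genes linked to a subset of planted windows,
* calibration tables (MS standard curves, qPCR standard curve) with known
  truth,

all recorded in a :class:`TruthTable` so that recovery can be scored.

Generative model for counts: window ``i`` in sample ``s`` draws
``NB(mean = depth_s * b_i * e_is, dispersion = phi)``, where ``b_i`` is a
log-normal per-window propensity shared by signal, input and WGA tracks
(making input normalization meaningful) and ``e_is`` is the planted
effect: ``gain_effect`` for gain windows in hypoxic signal tracks other
than the knockdown (the knockdown reverts the gain), 1 otherwise. WGA
artifact windows get an extra fold in the WGA track and a smaller extra
fold in hypoxic signal tracks.

Determinism: one master seed; every stream is a deterministic spawn of it,
so a fixed config reproduces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .windowing import CountMatrix, GenomeLayout, AlignedTag, Window, tile_genome

__all__ = [
    "SimConfig",
    "CalibConfig",
    "TruthTable",
    "CalibrationSim",
    "simulate_genome",
    "simulate_counts",
    "simulate_nb_matrix",
    "simulate_expression",
    "simulate_tags",
    "simulate_calibration",
]

CONDITIONS = ("normoxia", "hypoxia", "hypoxia_kd", "hypoxia_ctrl")
#: Hypoxic signal tracks that carry the planted gain (the knockdown reverts it).
GAIN_CONDITIONS = ("hypoxia", "hypoxia_ctrl")
HYPOXIC_CONDITIONS = ("hypoxia", "hypoxia_kd", "hypoxia_ctrl")


@dataclass(frozen=True)
class SimConfig:
    """World description for the sequencing simulation.

    Defaults state the scenario the pipeline is built for: a 15 Mb toy
    genome tiled into 5000 3-kb windows, triplicate libraries (five
    hypoxia signal replicates, enabling two replicate-subset comparisons),
    50 expected tags per window, 2% planted gain windows at a 2-fold
    hypoxia effect, and 2% planted WGA amplification artifacts.
    """

    n_chroms: int = 2
    chrom_length: int = 7_500_000
    window_width: int = 3000
    n_replicates: int = 3
    n_hypoxia_signal_replicates: int = 5
    mean_depth: float = 50.0
    dispersion_true: float = 0.01
    gain_fraction: float = 0.02
    gain_effect: float = 2.0
    wga_artifact_fraction: float = 0.02
    wga_artifact_effect_wga: float = 3.0
    wga_artifact_effect_signal: float = 2.0
    input_bias_sd: float = 0.5
    gene_spacing: int = 10_000
    expr_n_genes_de: int = 50
    expr_effect: float = 2.0
    expr_mean: float = 100.0
    seed: int = 0

    def __post_init__(self):
        for name in ("gain_fraction", "wga_artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.gain_effect < 1.0:
            raise ValueError("gain_effect must be >= 1")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.dispersion_true < 0:
            raise ValueError("dispersion must be >= 0")
        if self.mean_depth <= 0 or self.mean_depth > 1e7:
            raise ValueError("mean_depth out of supported range (0, 1e7]")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stream generator spawned from the master seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class TruthTable:
    """Planted effects: the acceptance surface for recovery tests.

    ``windows`` is indexed by window id with columns ``is_gain``,
    ``is_wga_artifact``, ``effect``; ``genes`` by gene id with ``is_de``
    and ``linked_window`` (the gain window driving the gene, or None).
    """

    windows: pd.DataFrame
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["is_de", "linked_window"])
    )

    def __post_init__(self):
        both = self.windows["is_gain"] & self.windows["is_wga_artifact"]
        if both.any():
            raise ValueError("gain and WGA-artifact window sets must be disjoint")
        linked = self.genes["linked_window"].dropna()
        unknown = set(linked) - set(self.windows.index)
        if unknown:
            raise ValueError(f"linked windows missing from truth: {sorted(unknown)}")

    @property
    def gain_ids(self) -> set[str]:
        return set(self.windows.index[self.windows["is_gain"]])

    @property
    def artifact_ids(self) -> set[str]:
        return set(self.windows.index[self.windows["is_wga_artifact"]])

    def to_json_dict(self) -> dict:
        return {
            "windows": {
                wid: {
                    "is_gain": bool(r.is_gain),
                    "is_wga_artifact": bool(r.is_wga_artifact),
                    "effect": float(r.effect),
                }
                for wid, r in self.windows.iterrows()
            },
            "genes": {
                gid: {
                    "is_de": bool(r.is_de),
                    "linked_window": None if pd.isna(r.linked_window) else str(r.linked_window),
                }
                for gid, r in self.genes.iterrows()
            },
        }


def simulate_genome(config: SimConfig) -> tuple[GenomeLayout, list[GeneModel]]:
    """Toy genome layout plus gene models with TSS, exons and UTRs.

    Genes are laid down along each chromosome with exponential spacing
    (mean ``gene_spacing``) and lengths of 2-8 kb, covering roughly a
    third of the genome; each has 2-5 exons and terminal 200 bp UTRs.
    """
    layout = GenomeLayout(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)
    )
    rng = config.rng(0)
    models: list[GeneModel] = []
    k = 0
    for chrom, length in layout.chroms:
        pos = int(rng.exponential(config.gene_spacing / 2)) + 200
        while True:
            gene_len = int(rng.integers(2000, 8001))
            if pos + gene_len >= length - 200:
                break
            k += 1
            start, end = pos, pos + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(1, gene_len), 2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [gene_len]])
            exons = tuple(
                (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
                for j in range(n_exons)
            )
            utr_len = 200
            first, last = exons[0], exons[-1]
            utrs = []
            if first[1] - first[0] > utr_len:
                utrs.append((first[0], first[0] + utr_len))
            if last[1] - last[0] > utr_len:
                utrs.append((last[1] - utr_len, last[1]))
            models.append(
                GeneModel(
                    gene_id=f"gene{k:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    utrs=tuple(utrs),
                )
            )
            pos = end + int(rng.exponential(config.gene_spacing)) + 200
    return layout, models


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) draws; Poisson when phi == 0."""
    mean = np.asarray(mean, dtype=float)
    if not np.all(np.isfinite(mean)):
        raise ValueError("NB mean overflow")
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    config: SimConfig,
    layout: GenomeLayout | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """Multi-condition, multi-track window counts plus the truth table.

    Samples: signal libraries for all four conditions (five hypoxia
    replicates, ``n_replicates`` elsewhere), matched inputs per condition,
    and a hypoxia WGA track. Gain windows and WGA-artifact windows are
    disjoint draws of the configured fractions.
    """
    if layout is None:
        layout = simulate_genome(config)[0]
    windows = tile_genome(layout, config.window_width)
    ids = [w.id for w in windows]
    n = len(windows)
    rng_truth = config.rng(1)
    rng_counts = config.rng(2)

    n_gain = round(config.gain_fraction * n)
    n_art = round(config.wga_artifact_fraction * n)
    chosen = rng_truth.choice(n, size=n_gain + n_art, replace=False)
    gain_idx = np.sort(chosen[:n_gain])
    art_idx = np.sort(chosen[n_gain:])
    is_gain = np.zeros(n, dtype=bool)
    is_gain[gain_idx] = True
    is_art = np.zeros(n, dtype=bool)
    is_art[art_idx] = True
    effect = np.where(is_gain & (config.gain_effect > 1.0), config.gain_effect, 1.0)

    # shared per-window propensity, normalized to unit mean
    b = rng_counts.lognormal(-config.input_bias_sd**2 / 2, config.input_bias_sd, size=n)

    samples: list[tuple[str, str, str, int]] = []
    for cond in CONDITIONS:
        n_sig = (
            config.n_hypoxia_signal_replicates if cond == "hypoxia" else config.n_replicates
        )
        samples += [(f"{cond}_signal_{r + 1}", cond, "signal", r + 1) for r in range(n_sig)]
    for cond in CONDITIONS:
        samples += [
            (f"{cond}_input_{r + 1}", cond, "input", r + 1)
            for r in range(config.n_replicates)
        ]
    samples += [
        (f"hypoxia_wga_{r + 1}", "hypoxia", "wga", r + 1)
        for r in range(config.n_replicates)
    ]

    data = {}
    for name, cond, track, _rep in samples:
        e = np.ones(n)
        if track == "signal" and cond in GAIN_CONDITIONS and config.gain_effect > 1.0:
            e = np.where(is_gain, config.gain_effect, e)
        if track == "signal" and cond in HYPOXIC_CONDITIONS:
            e = np.where(is_art, e * config.wga_artifact_effect_signal, e)
        if track == "wga":
            e = np.where(is_art, e * config.wga_artifact_effect_wga, e)
        mean = config.mean_depth * b * e
        data[name] = _nb_draw(rng_counts, mean, config.dispersion_true)

    counts = pd.DataFrame(data, index=pd.Index(ids, name="window"))
    sheet = pd.DataFrame(
        [(cond, track, rep) for _, cond, track, rep in samples],
        index=pd.Index([s[0] for s in samples], name="sample"),
        columns=["condition", "track", "replicate"],
    )
    truth_windows = pd.DataFrame(
        {
            "is_gain": is_gain if config.gain_effect > 1.0 else np.zeros(n, dtype=bool),
            "is_wga_artifact": is_art,
            "effect": effect,
        },
        index=pd.Index(ids, name="window"),
    )
    return CountMatrix(counts=counts, samples=sheet), TruthTable(windows=truth_windows)


def simulate_nb_matrix(
    n_units: int,
    n_per_group: tuple[int, int],
    mu_range: tuple[float, float],
    phi: float,
    seed: int,
    effect: float = 1.0,
    n_effect_units: int = 0,
) -> tuple[CountMatrix, dict[str, str], np.ndarray]:
    """Plain two-group NB matrix for statistical calibration checks.

    Per-unit means are log-uniform over ``mu_range``; the first
    ``n_effect_units`` units get ``effect``-fold higher means in group B.
    Returns the matrix, a sample->group mapping, and the unit means.
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    mu = np.exp(rng.uniform(math.log(mu_range[0]), math.log(mu_range[1]), size=n_units))
    fold = np.ones(n_units)
    fold[:n_effect_units] = effect
    cols, groups = {}, {}
    for j in range(n_a):
        name = f"A_{j + 1}"
        cols[name] = _nb_draw(rng, mu, phi)
        groups[name] = "A"
    for j in range(n_b):
        name = f"B_{j + 1}"
        cols[name] = _nb_draw(rng, mu * fold, phi)
        groups[name] = "B"
    counts = pd.DataFrame(cols, index=[f"u{i}" for i in range(n_units)])
    sheet = pd.DataFrame(
        {"condition": list(groups.values()), "track": "signal", "replicate": 1},
        index=pd.Index(list(groups), name="sample"),
    )
    lib = counts.sum(axis=0).astype(float)
    # treat expected depth as the library size so equalization is mild
    return CountMatrix(counts, sheet, lib), groups, mu


def simulate_expression(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: TruthTable,
    cell_lines: Sequence[str] = ("lineA", "lineB"),
    promoter_bp: int = 10_000,
) -> tuple[dict[str, CountMatrix], TruthTable]:
    """Gene expression matrices with DE genes linked to planted gain windows.

    Genes whose body or upstream promoter window overlaps a planted gain
    window are candidates; ``expr_n_genes_de`` of them (all, if fewer) are
    planted as hypoxia-induced / knockdown-reverted in every cell line.
    Returns per-cell-line matrices and the truth table with its gene layer
    filled in.
    """
    rng = config.rng(3)
    gain = truth.gain_ids
    spans: dict[str, tuple[str, int, int]] = {}
    for wid in gain:
        chrom, se = wid.rsplit(":", 1)
        s, e = (int(x) for x in se.split("-"))
        spans[wid] = (chrom, s, e)

    linked: dict[str, str] = {}
    for g in models:
        if g.strand == "+":
            lo, hi = g.start - promoter_bp, g.end
        else:
            lo, hi = g.start, g.end + promoter_bp
        for wid, (chrom, s, e) in spans.items():
            if chrom == g.chrom and s < hi and e > max(lo, 0):
                linked[g.gene_id] = wid
                break
    candidates = sorted(linked)
    n_de = min(config.expr_n_genes_de, len(candidates))
    de_genes = (
        sorted(rng.choice(candidates, size=n_de, replace=False)) if n_de else []
    )
    de_set = set(de_genes)

    gene_ids = [g.gene_id for g in models]
    base = np.exp(rng.uniform(math.log(20), math.log(500), size=len(models)))
    is_de = np.array([g in de_set for g in gene_ids])
    mats: dict[str, CountMatrix] = {}
    for line in cell_lines:
        cols, rows = {}, []
        for cond in CONDITIONS:
            e = np.where(
                is_de & (cond in GAIN_CONDITIONS), config.expr_effect, 1.0
            )
            for r in range(config.n_replicates):
                name = f"{line}_{cond}_{r + 1}"
                cols[name] = _nb_draw(rng, base * e, config.dispersion_true)
                rows.append((name, cond, "rna", r + 1))
        counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
        sheet = pd.DataFrame(
            [(c, t, rep) for _, c, t, rep in rows],
            index=pd.Index([r[0] for r in rows], name="sample"),
            columns=["condition", "track", "replicate"],
        )
        mats[line] = CountMatrix(counts, sheet)

    genes = pd.DataFrame(
        {
            "is_de": is_de,
            "linked_window": [linked.get(g) for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return mats, TruthTable(windows=truth.windows, genes=genes)


def simulate_tags(
    config: SimConfig,
    layout: GenomeLayout,
    counts_vector: np.ndarray | None = None,
    duplicate_fraction: float = 0.0,
    stream: int = 4,
) -> list[AlignedTag]:
    """5'-end tags for one library, uniform within each window.

    When ``counts_vector`` is omitted, counts are drawn from the
    generative model with no planted effects. ``duplicate_fraction``
    resamples that share of tags as exact duplicates of existing ones, for
    exercising deduplication.
    """
    rng = config.rng(stream)
    windows = tile_genome(layout, config.window_width)
    if counts_vector is None:
        b = rng.lognormal(-config.input_bias_sd**2 / 2, config.input_bias_sd, len(windows))
        counts_vector = _nb_draw(rng, config.mean_depth * b, config.dispersion_true)
    tags: list[AlignedTag] = []
    for w, c in zip(windows, np.asarray(counts_vector)):
        if c <= 0:
            continue
        pos = rng.integers(w.start, w.end, size=int(c))
        strands = rng.random(int(c)) < 0.5
        for p, plus in zip(pos, strands):
            tags.append(AlignedTag(w.chrom, int(p), "+" if plus else "-", mapq=60))
    if duplicate_fraction > 0 and tags:
        n_dup = int(duplicate_fraction * len(tags))
        for i in rng.integers(0, len(tags), size=n_dup):
            tags.append(tags[int(i)])
    return tags


@dataclass(frozen=True)
class CalibConfig:
    """World description for the calibration simulation.

    MS truth: linear area-vs-amount responses for 6mA and dA and a sample
    with a true 6mA/dA ratio of 10 ppm. qPCR truth: an ideal-efficiency
    standard curve (slope -log2(10) per log10 = -3.3219 cycles/decade,
    intercept 40) and a sample holding 46 transcript copies per cell in
    500,000 cells.
    """

    n_standards: int = 6
    ms_slope_6ma: float = 2.0e3
    ms_slope_da: float = 1.5
    ms_intercept_6ma: float = 0.0
    ms_intercept_da: float = 0.0
    ms_noise_frac: float = 0.01
    true_ratio_ppm: float = 10.0
    da_amount: float = 1.0
    qpcr_slope: float = -3.3219
    qpcr_intercept: float = 40.0
    qpcr_log10_range: tuple[float, float] = (3.0, 8.0)
    ct_noise_sd: float = 0.1
    true_copies_per_cell: float = 46.0
    n_cells: int = 500_000
    #: technical replicates averaged for each sample measurement (MIQE-style
    #: triplicates; standards stay single-shot)
    n_technical_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.ms_noise_frac < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_standards < 2:
            raise ValueError("need at least 2 standard points")


@dataclass
class CalibrationSim:
    """Generated standards and sample measurements with recorded truth."""

    ms_standards_6ma: pd.DataFrame
    ms_standards_da: pd.DataFrame
    sample_area_6ma: float
    sample_area_da: float
    qpcr_standards: pd.DataFrame
    sample_ct: float
    truth: dict


def simulate_calibration(config: CalibConfig) -> CalibrationSim:
    """Linear MS and qPCR standards with additive Gaussian noise.

    MS noise is additive with sd equal to ``ms_noise_frac`` of the true
    response at each point ("1% noise"); Ct noise has sd ``ct_noise_sd``
    cycles. The sample measurements embed the configured true ppm ratio
    and copies per cell.
    """
    rng = np.random.default_rng(config.seed)

    def ms_table(slope, intercept, amounts):
        resp = slope * amounts + intercept
        noise = rng.normal(0.0, 1.0, size=amounts.size) * config.ms_noise_frac * np.abs(resp)
        return pd.DataFrame({"amount": amounts, "response": resp + noise})

    # standards bracket the sample amounts (6mA ~ ppm-level of the dA amount)
    amounts_6ma = np.geomspace(1e-6, 1e-4, config.n_standards)
    amounts_da = np.geomspace(0.05, 5.0, config.n_standards)
    std_6ma = ms_table(config.ms_slope_6ma, config.ms_intercept_6ma, amounts_6ma)
    std_da = ms_table(config.ms_slope_da, config.ms_intercept_da, amounts_da)

    def noisy_mean(true_value, sd):
        """Mean of the technical replicates of one sample measurement."""
        if sd == 0:
            return float(true_value)
        k = config.n_technical_replicates
        return float(true_value + rng.normal(0.0, sd, size=k).mean())

    amount_6ma = config.true_ratio_ppm * 1e-6 * config.da_amount
    area_6ma = noisy_mean(
        config.ms_slope_6ma * amount_6ma + config.ms_intercept_6ma,
        config.ms_noise_frac * abs(config.ms_slope_6ma * amount_6ma + config.ms_intercept_6ma),
    )
    area_da = noisy_mean(
        config.ms_slope_da * config.da_amount + config.ms_intercept_da,
        config.ms_noise_frac * abs(config.ms_slope_da * config.da_amount + config.ms_intercept_da),
    )

    log10_copies = np.linspace(*config.qpcr_log10_range, config.n_standards)
    ct = config.qpcr_intercept + config.qpcr_slope * log10_copies
    ct = ct + rng.normal(0.0, config.ct_noise_sd, size=ct.size)
    qpcr = pd.DataFrame({"log10_copies": log10_copies, "ct": ct})

    total_copies = config.true_copies_per_cell * config.n_cells
    sample_ct = noisy_mean(
        config.qpcr_intercept + config.qpcr_slope * math.log10(total_copies),
        config.ct_noise_sd,
    )

    truth = {
        "ms_slope_6ma": config.ms_slope_6ma,
        "ms_slope_da": config.ms_slope_da,
        "ratio_ppm": config.true_ratio_ppm,
        "qpcr_slope": config.qpcr_slope,
        "qpcr_intercept": config.qpcr_intercept,
        "copies_per_cell": config.true_copies_per_cell,
        "n_cells": config.n_cells,
    }
    return CalibrationSim(
        ms_standards_6ma=std_6ma,
        ms_standards_da=std_da,
        sample_area_6ma=float(area_6ma),
        sample_area_da=float(area_da),
        qpcr_standards=qpcr,
        sample_ct=float(sample_ct),
        truth=truth,
    )
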