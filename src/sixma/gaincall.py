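"""Gain-of-6mA region calling.

A window is a *gain-of-6mA region* when its 6mA ChIP-exo signal rises
under hypoxia, falls back when the methyltransferase (METTL4) is knocked
down, and survives two background subtractions: matched sequencing input
(chromatin abundance / mappability) and a whole-genome-amplification (WGA)
control (antibody-independent amplification bias).

Each :class:`ComparisonSpec` bundles one full gate set on one replicate
selection:

* exact-test p-value on hypoxia vs normoxia signal counts (``p < alpha``),
* input-normalized log2 fold change hypoxia vs normoxia ``> tau_up``,
* input-normalized log2 fold change knockdown vs control-knockdown under
  hypoxia ``< tau_down``.

The fold gates use ``tau = log2(1.1)``; the p gate applies to the
hypoxia-vs-normoxia contrast only. Final regions are the intersection of
all comparisons' passing windows with the hypoxia/WGA-positive set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import nbstat
from .windowing import CountMatrix

__all__ = [
    "TAU_DEFAULT",
    "ComparisonSpec",
    "GainRegionSet",
    "cpm",
    "input_normalized_log2fc",
    "condition_mean_cpm",
    "run_comparison",
    "wga_positive_windows",
    "call_gain_regions",
    "comparisons_from_sheet",
]

#: Default fold-change gate on input-normalized log2 ratios.
TAU_DEFAULT = math.log2(1.1)


def cpm(count, libsize):
    """Counts per million library tags."""
    count = np.asarray(count, dtype=float)
    libsize = np.asarray(libsize, dtype=float)
    if np.any(libsize <= 0):
        raise ValueError("library size must be positive")
    out = count / libsize * 1e6
    return float(out) if out.ndim == 0 else out


def input_normalized_log2fc(signal_cpm, input_cpm, pseudo: float = 1.0):
    """``log2((signal + pseudo) / (input + pseudo))`` on cpm values.

    Replicates are expected to be averaged within condition before the
    ratio (see :func:`condition_mean_cpm`). The pseudo-count bounds the
    ratio at zero coverage: 0 vs 0 gives exactly 0.
    """
    s = np.asarray(signal_cpm, dtype=float)
    i = np.asarray(input_cpm, dtype=float)
    if np.any(s < 0) or np.any(i < 0):
        raise ValueError("cpm values must be non-negative")
    out = np.log2((s + pseudo) / (i + pseudo))
    return float(out) if out.ndim == 0 else out


def condition_mean_cpm(counts: CountMatrix, sample_ids: Sequence[str]) -> pd.Series:
    """Mean cpm across the given replicate samples, per unit."""
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("no samples given")
    mat = counts.counts[sample_ids].to_numpy(dtype=float)
    libs = counts.lib_sizes[sample_ids].to_numpy(dtype=float)
    return pd.Series((mat / libs * 1e6).mean(axis=1), index=counts.unit_ids)


@dataclass
class ComparisonSpec:
    """One replicate selection with its full gain-of-6mA gate set.

    ``signal_a``/``input_a`` belong to condition A (normoxia),
    ``signal_b``/``input_b`` to condition B (hypoxia, possibly a replicate
    subset); ``kd_*`` and ``ctrl_*`` are methyltransferase knockdown and
    control knockdown under hypoxia.
    """

    name: str
    signal_a: list[str]
    signal_b: list[str]
    input_a: list[str]
    input_b: list[str]
    kd_signal: list[str]
    ctrl_signal: list[str]
    kd_input: list[str]
    ctrl_input: list[str]
    tau_up: float = TAU_DEFAULT
    tau_down: float = -TAU_DEFAULT
    alpha: float = 0.05
    pseudo_cpm: float = 1.0

    def __post_init__(self):
        if not self.tau_up > 0:
            raise ValueError("tau_up must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def run_comparison(
    counts: CountMatrix, spec: ComparisonSpec, phi: float | None = None
) -> pd.DataFrame:
    """Per-window statistics and pass flag for one comparison.

    p-values come from the NB exact test on the raw (library-size
    equalized) hypoxia vs normoxia signal counts; input normalization
    enters only the fold-change gates. Returns a DataFrame indexed by
    window id with columns ``p``, ``lfc_hn``, ``lfc_kd``, ``passed``.
    """
    for label, ids in [
        ("signal_a", spec.signal_a), ("signal_b", spec.signal_b),
        ("input_a", spec.input_a), ("input_b", spec.input_b),
        ("kd_signal", spec.kd_signal), ("ctrl_signal", spec.ctrl_signal),
        ("kd_input", spec.kd_input), ("ctrl_input", spec.ctrl_input),
    ]:
        missing = set(ids) - set(counts.sample_ids)
        if not ids or missing:
            raise ValueError(
                f"comparison {spec.name!r}: {label} unresolved "
                f"(missing {sorted(missing) if missing else 'all samples'})"
            )

    groups = {s: "A" for s in spec.signal_a} | {s: "B" for s in spec.signal_b}
    sig = counts.subset(spec.signal_a + spec.signal_b)
    if phi is None:
        est = nbstat.estimate_common_dispersion(sig, groups)
        phi, pseudo = est.phi, est.pseudo_counts
    else:
        pseudo, _ = nbstat.equalize_library_sizes(sig.counts, sig.lib_sizes, phi)
    ya = pseudo[spec.signal_a].to_numpy(dtype=float)
    yb = pseudo[spec.signal_b].to_numpy(dtype=float)
    pvals = np.empty(len(pseudo))
    for i in range(len(pseudo)):
        pvals[i] = nbstat.exact_test(nbstat.TwoGroupCounts(ya[i], yb[i]), phi).p

    mean = {
        "sig_a": condition_mean_cpm(counts, spec.signal_a),
        "sig_b": condition_mean_cpm(counts, spec.signal_b),
        "inp_a": condition_mean_cpm(counts, spec.input_a),
        "inp_b": condition_mean_cpm(counts, spec.input_b),
        "kd": condition_mean_cpm(counts, spec.kd_signal),
        "ctrl": condition_mean_cpm(counts, spec.ctrl_signal),
        "kd_inp": condition_mean_cpm(counts, spec.kd_input),
        "ctrl_inp": condition_mean_cpm(counts, spec.ctrl_input),
    }
    norm_a = input_normalized_log2fc(mean["sig_a"], mean["inp_a"], spec.pseudo_cpm)
    norm_b = input_normalized_log2fc(mean["sig_b"], mean["inp_b"], spec.pseudo_cpm)
    norm_kd = input_normalized_log2fc(mean["kd"], mean["kd_inp"], spec.pseudo_cpm)
    norm_ctrl = input_normalized_log2fc(mean["ctrl"], mean["ctrl_inp"], spec.pseudo_cpm)
    lfc_hn = norm_b - norm_a
    lfc_kd = norm_kd - norm_ctrl

    out = pd.DataFrame(
        {
            "p": pvals,
            "lfc_hn": lfc_hn,
            "lfc_kd": lfc_kd,
        },
        index=counts.unit_ids,
    )
    out["passed"] = (
        (out["p"] < spec.alpha)
        & (out["lfc_hn"] > spec.tau_up)
        & (out["lfc_kd"] < spec.tau_down)
    )
    out.attrs["comparison"] = spec.name
    out.attrs["phi"] = phi
    return out


def wga_positive_windows(
    counts: CountMatrix,
    hypoxia_signal: Sequence[str],
    wga_samples: Sequence[str],
    pseudo: float = 1.0,
    tau: float = TAU_DEFAULT,
) -> set[str]:
    """Windows whose hypoxia signal clears the WGA amplification background.

    A window is hypoxia/WGA positive when
    ``log2((hypoxia_cpm + pseudo) / (wga_cpm + pseudo)) > tau``. Windows
    whose apparent enrichment is reproduced by amplified naked DNA fail
    this gate and are discarded as artifacts.
    """
    if not list(wga_samples):
        raise ValueError("WGA track is absent")
    hyp = condition_mean_cpm(counts, hypoxia_signal)
    wga = condition_mean_cpm(counts, wga_samples)
    lfc = input_normalized_log2fc(hyp, wga, pseudo)
    return set(counts.unit_ids[np.asarray(lfc) > tau])


@dataclass
class GainRegionSet:
    """Final gain-of-6mA regions with per-window filter provenance.

    ``provenance`` is indexed by window id with one boolean column per
    comparison (``passed_<name>``) plus ``wga_positive``; ``regions`` are
    the ids passing every filter; ``stage_counts`` records the size of each
    passing set and of the final intersection.
    """

    regions: list[str]
    provenance: pd.DataFrame
    stage_counts: dict[str, int]


def call_gain_regions(
    comparisons: Sequence[pd.DataFrame],
    wga_set: Iterable[str],
    merge_adjacent: bool = False,
) -> GainRegionSet:
    """Intersect comparison passing sets with the WGA-positive set.

    All comparisons must share one window tiling (identical index). With
    ``merge_adjacent`` the emitted window ids are additionally grouped into
    maximal runs of adjacent windows (off by default; regions are reported
    at window granularity).
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("need at least one comparison")
    index = comparisons[0].index
    for c in comparisons[1:]:
        if not index.equals(c.index):
            raise ValueError("comparisons are on mismatched window tilings")
    wga_set = set(wga_set)

    prov = pd.DataFrame(index=index)
    stage_counts: dict[str, int] = {}
    passing = None
    for i, c in enumerate(comparisons):
        name = c.attrs.get("comparison", f"c{i + 1}")
        col = c["passed"].astype(bool)
        prov[f"passed_{name}"] = col
        stage_counts[name] = int(col.sum())
        ids = set(index[col])
        passing = ids if passing is None else (passing & ids)
    prov["wga_positive"] = [w in wga_set for w in index]
    stage_counts["wga_positive"] = len(wga_set & set(index))
    final = passing & wga_set
    regions = [w for w in index if w in final]  # tiling order
    stage_counts["gain_regions"] = len(regions)
    if merge_adjacent:
        regions = _merge_runs(regions)
    return GainRegionSet(regions=regions, provenance=prov, stage_counts=stage_counts)


def _merge_runs(window_ids: list[str]) -> list[str]:
    """Merge adjacent 'chrom:start-end' ids into maximal runs."""
    parsed = []
    for wid in window_ids:
        chrom, span = wid.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        parsed.append((chrom, start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(parsed):
        if merged and merged[-1][0] == chrom and merged[-1][2] == start:
            merged[-1] = (chrom, merged[-1][1], end)
        else:
            merged.append((chrom, start, end))
    return [f"{c}:{s}-{e}" for c, s, e in merged]


def comparisons_from_sheet(
    counts: CountMatrix,
    hypoxia_subsets: Sequence[Sequence[int]] = ((0, 1, 2), (0, 3, 4)),
    normoxia: str = "normoxia",
    hypoxia: str = "hypoxia",
    knockdown: str = "hypoxia_kd",
    control: str = "hypoxia_ctrl",
    **gate_kwargs,
) -> list[ComparisonSpec]:
    """Build the two-comparison design from a sample sheet.

    Mirrors the study design: hypoxia signal replicate subsets (by index
    into the hypoxia signal sample list, default replicates {1,2,3} and
    {1,4,5} of five) define one comparison each; all other tracks are
    shared between comparisons.
    """
    hyp_sig = counts.select_samples(hypoxia, "signal")
    specs = []
    for k, subset in enumerate(hypoxia_subsets, start=1):
        try:
            chosen = [hyp_sig[i] for i in subset]
        except IndexError:
            raise ValueError(
                f"hypoxia subset {tuple(subset)} exceeds the "
                f"{len(hyp_sig)} available hypoxia signal replicates"
            )
        specs.append(
            ComparisonSpec(
                name=f"comparison{k}",
                signal_a=counts.select_samples(normoxia, "signal"),
                signal_b=chosen,
                input_a=counts.select_samples(normoxia, "input"),
                input_b=counts.select_samples(hypoxia, "input"),
                kd_signal=counts.select_samples(knockdown, "signal"),
                ctrl_signal=counts.select_samples(control, "signal"),
                kd_input=counts.select_samples(knockdown, "input"),
                ctrl_input=counts.select_samples(control, "input"),
                **gate_kwargs,
            )
        )
    return specs
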