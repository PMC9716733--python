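"""NB conditional likelihood, qCML dispersion, equalization and exact test.

The exact-test oracle used here enumerates products of unconditional
scipy NB pmfs over all partitions of the grand total — a different route
from the implementation's closed-form conditional distribution.
"""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sixma import synthio
from sixma.nbstat import (
    TwoGroupCounts,
    call_de,
    conditional_log_likelihood,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_test,
)


def oracle_doubletail(y_a, y_b, phi, mu=None):
    """Exhaustive enumeration of P(S_A=a)P(S_B=b) over all a+b = s."""
    n_a, n_b = len(y_a), len(y_b)
    s = int(round(sum(y_a) + sum(y_b)))
    if s == 0:
        return 1.0
    if mu is None:
        mu = s / (n_a + n_b)
    a = np.arange(s + 1)
    if phi < 1e-6:
        pa = stats.poisson.pmf(a, n_a * mu)
        pb = stats.poisson.pmf(s - a, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        pa = stats.nbinom.pmf(a, r_a, r_a / (r_a + n_a * mu))
        pb = stats.nbinom.pmf(s - a, r_b, r_b / (r_b + n_b * mu))
    joint = pa * pb
    obs = joint[int(round(sum(y_a)))]
    return float(joint[joint <= obs * (1 + 1e-12)].sum() / joint.sum())


class TestConditionalLogLikelihood:
    def test_reference_value(self):
        # independent lgamma arithmetic: y=[3,5], phi=0.5 -> -5.953
        assert conditional_log_likelihood([3, 5], 0.5) == pytest.approx(-5.9533, abs=1e-3)

    def test_single_sample_is_constant(self):
        vals = {conditional_log_likelihood([7], phi) for phi in (0.01, 0.5, 2.0)}
        assert len(vals) == 1

    def test_poisson_limit(self):
        # phi -> 0 approaches -z*log(n), the multinomial conditional limit
        y = [4, 9, 2]
        lim = -sum(y) * math.log(3)
        assert conditional_log_likelihood(y, 1e-7) == pytest.approx(lim, abs=1e-3)
        assert conditional_log_likelihood(y, 0.0) == pytest.approx(lim)

    def test_rejects_negative_phi(self):
        with pytest.raises(ValueError):
            conditional_log_likelihood([1, 2], -0.1)


class TestEqualizeLibrarySizes:
    def test_equal_libs_identity(self):
        counts = pd.DataFrame({"a": [5, 10, 0], "b": [7, 3, 2]})
        libs = pd.Series({"a": 1000.0, "b": 1000.0})
        pseudo, n_star = equalize_library_sizes(counts, libs, phi=0.2)
        assert n_star == pytest.approx(1000.0)
        assert np.allclose(pseudo.to_numpy(), counts.to_numpy())

    def test_doubled_library_roughly_halves_count(self):
        counts = pd.DataFrame({"a": [100], "b": [200]})
        libs = pd.Series({"a": 1000.0, "b": 2000.0})
        pseudo, n_star = equalize_library_sizes(counts, libs, phi=0.1)
        assert n_star == pytest.approx(math.sqrt(2) * 1000)
        # both samples map to the same rate at N*; integer-quantile step ~ sd
        assert pseudo["a"][0] == pytest.approx(100 * n_star / 1000, abs=3)
        assert pseudo["b"][0] == pytest.approx(200 * n_star / 2000, abs=3)

    def test_monotone_and_nonnegative(self):
        y = np.arange(0, 60)
        counts = pd.DataFrame({"a": y, "b": np.full_like(y, 20)})
        libs = pd.Series({"a": 500.0, "b": 2000.0})
        pseudo, _ = equalize_library_sizes(counts, libs, phi=0.3)
        col = pseudo["a"].to_numpy()
        assert (col >= 0).all()
        assert (np.diff(col) >= 0).all()

    def test_zero_libsize_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            equalize_library_sizes(counts, pd.Series({"a": 0.0, "b": 10.0}), 0.1)


class TestCommonDispersion:
    def test_recovers_truth(self):
        cm, groups, _ = synthio.simulate_nb_matrix(2000, (3, 3), (20, 200), 0.2, seed=42)
        est = estimate_common_dispersion(cm, groups)
        assert abs(est.phi - 0.2) < 0.05

    def test_poisson_boundary(self):
        cm, groups, _ = synthio.simulate_nb_matrix(2000, (3, 3), (20, 200), 0.0, seed=7)
        assert estimate_common_dispersion(cm, groups).phi <= 0.01

    def test_identical_unit_additivity(self):
        # duplicating one unit 100x rescales the likelihood, not its argmax
        one = pd.DataFrame({"a1": [5], "a2": [5], "b1": [5], "b2": [5]})
        many = pd.concat([one] * 100, ignore_index=True)
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        libs = pd.Series(1000.0, index=one.columns)
        phi1 = estimate_common_dispersion(one, groups, libs).phi
        phi100 = estimate_common_dispersion(many, groups, libs).phi
        assert phi1 == pytest.approx(phi100, abs=1e-4)

    def test_all_zero_is_an_error(self):
        zero = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        libs = pd.Series({"a": 10.0, "b": 10.0})
        with pytest.raises(ValueError, match="no information"):
            estimate_common_dispersion(zero, {"a": "A", "b": "A"}, libs)


class TestExactTest:
    def test_balanced_split_is_p_one(self):
        r = exact_test(TwoGroupCounts([2], [2]), 1e-8)
        assert r.p == pytest.approx(1.0)

    def test_binomial_doubletail_limit(self):
        r = exact_test(TwoGroupCounts([0], [10]), 1e-8)
        assert r.p == pytest.approx(2 / 1024, abs=1e-9)

    @pytest.mark.parametrize("phi", [1e-8, 0.05, 0.5, 2.0])
    @pytest.mark.parametrize("y_a, y_b", [([0], [10]), ([3, 1], [9, 8]), ([5, 0, 2], [1, 1])])
    def test_matches_enumeration_oracle(self, phi, y_a, y_b):
        r = exact_test(TwoGroupCounts(y_a, y_b), phi)
        assert r.p == pytest.approx(oracle_doubletail(y_a, y_b, phi), abs=1e-12)

    @given(
        st.lists(st.integers(0, 30), min_size=1, max_size=3),
        st.lists(st.integers(0, 30), min_size=1, max_size=3),
        st.sampled_from([1e-8, 0.1, 1.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, y_a, y_b, phi):
        fwd = exact_test(TwoGroupCounts(y_a, y_b), phi)
        rev = exact_test(TwoGroupCounts(y_b, y_a), phi)
        assert fwd.p == pytest.approx(rev.p, rel=1e-9)
        assert fwd.log2fc == pytest.approx(-rev.log2fc, rel=1e-9)
        assert 0 < fwd.p <= 1

    def test_zero_total_convention(self):
        r = exact_test(TwoGroupCounts([0, 0], [0]), 0.1)
        assert r.p == 1.0 and r.log2fc == 0.0


class TestCallDe:
    def _matrix(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=200).astype(float)
        cols = {}
        for s in ["a1", "a2", "a3"]:
            cols[s] = rng.poisson(base)
        for s in ["b1", "b2", "b3"]:
            fold = np.ones(200)
            fold[:20] = 3.0
            cols[s] = rng.poisson(base * fold)
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(200)])
        sheet = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3, "track": "rna", "replicate": [1, 2, 3] * 2},
            index=counts.columns,
        )
        from sixma.windowing import CountMatrix

        return CountMatrix(counts, sheet), {s: ("A" if s.startswith("a") else "B") for s in cols}

    def test_flags_follow_thresholds(self):
        cm, groups = self._matrix()
        de = call_de(cm, groups, ("A", "B"))
        assert (de.loc[[f"g{i}" for i in range(20)], "flag"] == "up").mean() > 0.8
        tau = math.log2(1.3)
        for _, row in de.iterrows():
            if row.flag == "up":
                assert row.log2fc > tau and row.p < 0.05
            elif row.flag == "down":
                assert row.log2fc < -tau and row.p < 0.05

    def test_permutation_invariance(self):
        cm, groups = self._matrix()
        de1 = call_de(cm, groups, ("A", "B"))
        shuffled = cm.subset(["a3", "a1", "a2", "b2", "b3", "b1"])
        de2 = call_de(shuffled, groups, ("A", "B"))
        assert (de1["flag"] == de2["flag"]).all()

    def test_unknown_group_rejected(self):
        cm, groups = self._matrix()
        with pytest.raises(ValueError, match="unknown group"):
            call_de(cm, groups, ("A", "C"))


class TestEdgeRCrossCheck:
    """Independent validation against Bioconductor edgeR (qCML + exact test)."""

    def test_dispersion_and_pvalues_match(self, tmp_path):
        cm, groups, _ = synthio.simulate_nb_matrix(
            300, (3, 3), (20, 200), 0.15, seed=5, effect=2.0, n_effect_units=30
        )
        counts_path = tmp_path / "counts.tsv"
        out_path = tmp_path / "edger.tsv"
        cm.counts.to_csv(counts_path, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- read.delim('{counts_path}', row.names=1)\n"
            "d <- DGEList(counts=x, group=factor(c('A','A','A','B','B','B')))\n"
            "d <- estimateCommonDisp(d)\n"
            "et <- exactTest(d, pair=c('A','B'))\n"
            "out <- data.frame(unit=rownames(et$table), logFC=et$table$logFC, p=et$table$PValue)\n"
            f"write.table(out, '{out_path}', sep='\\t', row.names=FALSE, quote=FALSE)\n"
            "cat(d$common.dispersion)\n"
        )
        try:
            proc = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=300
            )
        except FileNotFoundError:
            pytest.skip("Rscript not on PATH")
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[-200:]}")
        edger_phi = float(proc.stdout.strip().split()[-1])
        ours = call_de(cm, groups, ("A", "B"))
        est = estimate_common_dispersion(cm, groups)
        edger = pd.read_csv(out_path, sep="\t", index_col=0)
        merged = ours.join(edger, rsuffix="_edger")
        assert abs(est.phi - edger_phi) < 0.005
        rel = (merged["p"] - merged["p_edger"]).abs() / merged["p_edger"]
        assert rel.median() < 0.05
        assert ((merged["p"] < 0.05) == (merged["p_edger"] < 0.05)).mean() >= 0.99
        assert (merged["log2fc"] - merged["logFC"]).abs().max() < 0.1
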