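"""Interspecific comparison statistics: exact rank-sum, Bonferroni t,
frequency-by-species linear model."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipitune.stats import (
    bonferroni_t,
    exact_wilcoxon,
    frequency_interaction_lm,
    rank_sum_null_counts,
)


def brute_force_p(x, y):
    """Enumerate every C(n1+n2, n1) rank assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1  # tie-free by construction
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(n), n1):
        r = sum(i + 1 for i in idx)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lower = int(np.sum(us <= u_obs))
    upper = int(np.sum(us >= u_obs))
    return float(min(1, 2 * min(Fraction(lower, len(us)), Fraction(upper, len(us)))))


class TestExactWilcoxon:
    def test_two_vs_two_complete_separation(self):
        res = exact_wilcoxon([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.statistic == 0
        assert res.p_two_sided == pytest.approx(2 / 6)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 2), (3, 3), (4, 3), (5, 4), (6, 6)])
    def test_agrees_with_brute_force_enumeration(self, n1, n2, rng):
        for _ in range(5):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(-1, 1)
            res = exact_wilcoxon(x, y)
            assert res.method == "exact"
            assert res.p_two_sided == pytest.approx(brute_force_p(x, y), abs=1e-12)

    def test_complete_separation_formula_at_study_sizes(self, rng):
        x = rng.uniform(0, 1, 12)
        y = rng.uniform(2, 3, 13)
        res = exact_wilcoxon(x, y)
        assert res.p_two_sided == pytest.approx(2 / comb(25, 12), rel=1e-12)
        # cross-check against scipy's exact implementation (identical here)
        from scipy.stats import mannwhitneyu

        assert res.p_two_sided == pytest.approx(
            float(mannwhitneyu(x, y, method="exact").pvalue), rel=1e-12
        )

    def test_reference_peak_comparison(self, reference_table):
        mel = reference_table.query("species=='melanogaster' and individual_id!='Average'")
        sim = reference_table.query("species=='simulans' and individual_id!='Average'")
        res = exact_wilcoxon(mel["peak_ipi_ms"], sim["peak_ipi_ms"])
        # printed values carry three significant digits
        assert res.p_two_sided == pytest.approx(3.85e-7, rel=2e-3)
        assert res.p_two_sided == pytest.approx(2 / comb(25, 12), rel=1e-12)
        res_tb = exact_wilcoxon(mel["tau_b"], sim["tau_b"])
        assert res_tb.p_two_sided == pytest.approx(1.54e-6, rel=2e-3)
        assert res_tb.p_two_sided == pytest.approx(8 / comb(25, 12), rel=1e-12)

    def test_null_counts_sum_to_binomial(self):
        for n1, n2 in [(3, 5), (6, 6), (12, 13)]:
            counts = rank_sum_null_counts(n1, n2)
            assert sum(counts) == comb(n1 + n2, n1)
            assert counts == counts[::-1]  # symmetry of the null

    @given(
        scale=st.floats(min_value=0.1, max_value=50),
        shift=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(6)
        y = rng.standard_normal(7) + 0.5
        base = exact_wilcoxon(x, y)
        lin = exact_wilcoxon(scale * x + shift, scale * y + shift)
        expd = exact_wilcoxon(np.exp(x), np.exp(y))
        assert lin.p_two_sided == base.p_two_sided
        assert expd.p_two_sided == base.p_two_sided

    def test_null_rejection_rate_at_most_nominal(self):
        """Exactness: under H0 the test rejects at 5% in <= 5% of datasets."""
        n1, n2 = 8, 9
        counts = np.array(rank_sum_null_counts(n1, n2), dtype=float)
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        sf = np.cumsum(counts[::-1])[::-1] / total
        p_of_u = np.minimum(1.0, 2 * np.minimum(cdf, sf))
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 10_000
        for _ in range(n_sim):
            pooled = rng.standard_normal(n1 + n2)
            ranks = np.argsort(np.argsort(pooled)) + 1
            u = int(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
            rejections += p_of_u[u] <= 0.05
        assert rejections / n_sim <= 0.05

    def test_ties_fall_back_to_permutation(self):
        res = exact_wilcoxon([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], n_permutations=2000, seed=1)
        assert res.method == "mid-rank-permutation"
        assert 0 < res.p_two_sided <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            exact_wilcoxon([], [1.0])


class TestBonferroniT:
    def test_identical_groups_give_one(self):
        g = {15.0: [0.1, 0.2, 0.3], 35.0: [0.0, 0.1, 0.2]}
        out = bonferroni_t(g, g)
        assert np.allclose(out["p_adjusted"], 1.0)

    def test_multiplication_rule_and_cap(self):
        rng = np.random.default_rng(0)
        base = {float(ipi): rng.normal(0, 0.01, 12) for ipi in range(1, 10)}
        shifted = {k: v + (0.05 if k == 1.0 else 0.0) for k, v in base.items()}
        out = bonferroni_t(base, shifted).set_index("ipi_ms")
        assert np.allclose(out["p_adjusted"], np.minimum(1.0, out["p_raw"] * 9))

    def test_degenerate_zero_variance_equal_means(self):
        g = {15.0: [0.2, 0.2, 0.2]}
        out = bonferroni_t(g, g)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_shift_only_at_15ms_detected_selectively(self):
        """Power: a true drop difference only at the shortest IPI is flagged
        there, and only there, in most replicates at the study sample sizes."""
        rng = np.random.default_rng(2024)
        ipis = [float(v) for v in (15, 35, 45, 55, 65, 75, 85, 95, 105)]
        hits, clean = 0, 0
        n_rep = 60
        for _ in range(n_rep):
            mel = {ipi: rng.normal(0.05, 0.01, 12) for ipi in ipis}
            sim = {
                ipi: rng.normal(0.05 + (0.02 if ipi == 15.0 else 0.0), 0.01, 13)
                for ipi in ipis
            }
            out = bonferroni_t(mel, sim).set_index("ipi_ms")
            sig = out[out["p_adjusted"] < 0.05].index.tolist()
            hits += 15.0 in sig
            clean += sig == [15.0]
        assert hits / n_rep >= 0.9
        assert clean / n_rep >= 0.8


class TestFrequencyInteraction:
    @staticmethod
    def frame(resp_mel, resp_sim, freqs=(100.0, 200.0, 300.0)):
        rows = []
        for sp, resp in (("melanogaster", resp_mel), ("simulans", resp_sim)):
            for i, ind in enumerate(resp):
                for f, v in zip(freqs, ind):
                    rows.append({"species": sp, "frequency_hz": f, "response": v})
        return pd.DataFrame(rows)

    def test_identical_species_zero_interaction(self):
        resp = [[0.5, 0.3, 0.1], [0.6, 0.35, 0.15]]
        out = frequency_interaction_lm(self.frame(resp, resp))
        inter = out[out["term"].str.contains(":")]["estimate"].iloc[0]
        assert inter == pytest.approx(0.0, abs=1e-12)

    def test_exact_slopes_recovered(self):
        freqs = np.array([100.0, 200.0, 300.0])
        s1, s2 = -2e-3, -0.7e-3
        mel = [list(1.0 + s1 * freqs)]
        sim = [list(0.8 + s2 * freqs)]
        out = frequency_interaction_lm(self.frame(mel * 2, sim * 2))
        inter = out[out["term"].str.contains(":")].iloc[0]
        assert inter["estimate"] == pytest.approx(s2 - s1, abs=1e-12)

    def test_recovery_within_two_se(self):
        rng = np.random.default_rng(31)
        freqs = np.array([100.0, 200.0, 300.0])
        true_inter = 3.3e-3
        mel = [list(0.9 - 3e-3 * freqs + rng.normal(0, 0.05, 3)) for _ in range(12)]
        sim = [
            list(0.7 + (-3e-3 + true_inter) * freqs + rng.normal(0, 0.05, 3))
            for _ in range(13)
        ]
        out = frequency_interaction_lm(self.frame(mel, sim))
        inter = out[out["term"].str.contains(":")].iloc[0]
        assert abs(inter["estimate"] - true_inter) < 2 * inter["std_error"]

    def test_single_frequency_rejected(self):
        df = self.frame([[0.5]], [[0.4]], freqs=(100.0,))
        with pytest.raises(ValueError):
            frequency_interaction_lm(df)
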