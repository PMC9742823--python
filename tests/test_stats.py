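"""Regression and ANOVA-heritability statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from rosettearea.stats import anova_h2, ols_fit
from rosettearea.synthetic import simulate_factorial_areas


class TestOls:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = ols_fit(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones(5), np.random.default_rng(0).normal(size=5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ols_fit(np.arange(4.0), np.arange(5.0))

    def test_matches_normal_equation_oracle_on_noisy_data(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 50, 20)
        y = 0.87 * x - 1.1 + rng.normal(0, 2.0, 20)
        res = ols_fit(x, y)
        # oracle: explicit (X'X)^-1 X'y
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        assert res.intercept == pytest.approx(beta[0], abs=1e-9)
        assert res.slope == pytest.approx(beta[1], abs=1e-9)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)


def brute_force_type1_ss(df):
    """Sequential sums of squares by explicit projection (oracle)."""
    y = df["area"].to_numpy(float)
    n = len(y)

    def dummies(labels):
        return pd.get_dummies(labels).to_numpy(float)

    blocks = [
        np.ones((n, 1)),
        dummies(df["genotype"]),
        dummies(df["n_source"]),
        dummies(df["n_source"].astype(str) + ":" + df["n_conc"].astype(str)),
    ]
    ss = []
    prev_rss = np.sum((y - y.mean()) ** 2) + 0.0
    X = blocks[0]
    base_rss = None
    for b in blocks[1:]:
        X = np.column_stack([X, b])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = np.sum((y - X @ beta) ** 2)
        if base_rss is None:
            base_rss = np.sum((y - y.mean()) ** 2)
            ss.append(base_rss - rss)
        else:
            ss.append(prev_rss - rss)
        prev_rss = rss
    return ss, prev_rss  # [genotype, source, treatment], residual


class TestAnovaH2:
    def test_identical_areas_degenerate_to_zero(self):
        df = simulate_factorial_areas(n_genotypes=5, seed=0)
        df["area"] = 7.0
        res = anova_h2(df)
        assert res.degenerate and res.h_squared == 0.0
        assert (res.table["sum_sq"] == 0).all()

    def test_pure_genotype_signal_gives_h2_of_one(self):
        df = simulate_factorial_areas(n_genotypes=8, seed=1)
        df["area"] = df["genotype"].str[1:].astype(int).astype(float)
        res = anova_h2(df)
        assert res.h_squared == pytest.approx(1.0, abs=1e-9)

    def test_single_genotype_rejected(self):
        df = simulate_factorial_areas(n_genotypes=5, seed=0)
        with pytest.raises(ValueError):
            anova_h2(df[df["genotype"] == "g0001"])

    def test_ss_decomposition_matches_brute_force_oracle(self):
        df = simulate_factorial_areas(n_genotypes=12, n_reps=2, seed=5)
        res = anova_h2(df)
        ss, resid = brute_force_type1_ss(df)
        got = res.table["sum_sq"]
        assert got["C(genotype)"] == pytest.approx(ss[0], rel=1e-9)
        assert got["C(n_source)"] == pytest.approx(ss[1], rel=1e-9)
        assert got["C(treatment)"] == pytest.approx(ss[2], rel=1e-9)
        assert got["Residual"] == pytest.approx(resid, rel=1e-9)

    def test_ss_sums_to_total(self):
        df = simulate_factorial_areas(n_genotypes=20, seed=2)
        res = anova_h2(df)
        assert res.table["sum_sq"].sum() == pytest.approx(res.total_ss, rel=1e-9)

    def test_h2_invariant_to_affine_area_rescaling(self):
        df = simulate_factorial_areas(n_genotypes=15, seed=3)
        h2 = anova_h2(df).h_squared
        df2 = df.assign(area=3.7 * df["area"] + 12.0)
        assert anova_h2(df2).h_squared == pytest.approx(h2, rel=1e-9)

    def test_recovers_simulated_genotype_fraction(self):
        df = simulate_factorial_areas(n_genotypes=100, n_reps=2,
                                      genotype_var_fraction=0.3, seed=11)
        res = anova_h2(df)
        assert res.h_squared == pytest.approx(0.3, abs=0.05)
        ss, _ = brute_force_type1_ss(df)
        assert res.h_squared == pytest.approx(ss[0] / res.total_ss, abs=1e-9)

    def test_mean_h2_tracks_simulated_fraction_monotonically(self):
        means = []
        for frac in (0.1, 0.3, 0.5):
            vals = [
                anova_h2(simulate_factorial_areas(
                    n_genotypes=40, n_reps=2,
                    genotype_var_fraction=frac, seed=s)).h_squared
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_unbalanced_table_still_decomposes(self):
        df = simulate_factorial_areas(n_genotypes=10, n_reps=2, seed=4)
        df = df.drop(df.index[::7])  # knock out some seedlings
        res = anova_h2(df)
        assert res.table["sum_sq"].sum() == pytest.approx(res.total_ss, rel=1e-9)
        assert 0.0 <= res.h_squared <= 1.0
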