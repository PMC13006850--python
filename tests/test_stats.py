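"""Statistical layer: correlations, FDR, GLMMs, ICC, bootstrap, power."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnocog import (
    BehaviorSimSpec,
    bootstrap_icc_ci,
    correlate,
    fdr_adjust,
    fit_glmm,
    icc_from_variances,
    latent_icc,
    simulate_behavior,
    simulate_power,
    summarize_participants,
)
from somnocog.stats import _fit_gaussian_ri, robust_z_outliers


def ri_dataset(seed=0, n=17, d=11, beta=None, vb=2404.27, vw=1440.80):
    """Random-intercept dataset with a sleep-scale predictor column."""
    rng = np.random.default_rng(seed)
    df = simulate_behavior(
        BehaviorSimSpec(n, d, beta0=430.0, var_between=vb, var_within=vw, seed=seed)
    )
    df["so_density"] = rng.normal(4.2, 2.0, len(df))
    if beta:
        df["outcome"] = df["outcome"] + beta * df["so_density"]
    return df


class TestSummaries:
    def test_mean_sd_per_participant(self):
        df = pd.DataFrame(
            {"participant": ["a", "a", "b"], "night": [0, 1, 0], "waso_min": [40.0, 60.0, 30.0]}
        )
        out = summarize_participants(df).set_index("participant")
        assert out.loc["a", "waso_min_mean"] == 50.0
        assert out.loc["a", "waso_min_std"] == pytest.approx(np.std([40, 60], ddof=1))
        assert np.isnan(out.loc["b", "waso_min_std"])  # single night

    def test_constant_metric_has_zero_sd(self):
        df = pd.DataFrame({"participant": ["a"] * 4, "night": range(4), "x": [7.0] * 4})
        out = summarize_participants(df)
        assert out["x_std"].iloc[0] == 0.0


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman(self):
        x = np.linspace(-2, 2, 15)
        r, _ = correlate(x, x**3, "spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_matches_permutation_oracle(self):
        """Two-tailed Pearson p on n=17 agrees with a 10,000-permutation
        null within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=17)
        y = 0.5 * x + rng.normal(size=17)
        r, p = correlate(x, y, "pearson")
        perm_r = np.empty(10_000)
        for i in range(10_000):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.sum(np.abs(perm_r) >= abs(r)) + 1) / (10_000 + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 10_000)
        assert abs(p - p_perm) < mc_err + 0.005


class TestFdr:
    def test_hand_worked_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert fdr_adjust([0.123]) == pytest.approx([0.123])
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_matches_bruteforce_stepup_oracle(self, pvals):
        """Step-up definition applied literally: adj_(i) is the minimum over
        j ≥ i of p_(j)·m/j (sorted), capped at 1."""
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            ]
            brute[idx] = min(1.0, min(candidates))
        assert np.allclose(fdr_adjust(p), brute)
        assert np.all(fdr_adjust(p) >= p - 1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        _, adj, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_adjust(p), adj)


class TestIcc:
    def test_reliability_from_variance_components(self):
        """Between 2404.27 and within 1440.80 give ICC 0.63 to two decimals."""
        assert round(icc_from_variances(2404.27, 1440.80), 2) == 0.63

    def test_edge_cases(self):
        assert icc_from_variances(0.0, 5.0) == 0.0
        assert icc_from_variances(3.0, 3.0) == 0.5
        with pytest.raises(ValueError):
            icc_from_variances(0.0, 0.0)

    def test_latent_scale_conventions(self):
        assert latent_icc(0.21, 1.0) == pytest.approx(0.21 / 1.21)
        assert latent_icc(0.21, np.pi**2 / 3) == pytest.approx(0.0600, abs=5e-4)
        assert latent_icc(0.0) == 0.0


class TestGaussianGlmm:
    def test_fast_fitter_matches_mixedlm(self):
        """The profiled-ML fitter and statsmodels MixedLM (ML) agree on
        coefficients, variance components and log-likelihood."""
        df = ri_dataset(seed=3, beta=-5.0)
        res = fit_glmm(df, "outcome", ["so_density"])
        X = np.column_stack([np.ones(len(df)), df["so_density"]])
        fast = _fit_gaussian_ri(df["outcome"].to_numpy(), X, df["participant"].to_numpy())
        assert np.allclose(res.fixed_effects["estimate"], fast["beta"], atol=1e-3)
        assert np.allclose(res.fixed_effects["se"], fast["se"], rtol=1e-3)
        assert res.loglik == pytest.approx(fast["loglik"], abs=1e-4)
        assert res.var_within == pytest.approx(fast["var_within"], rel=1e-3)

    def test_known_slope_recovered(self):
        """β = −5 per density unit is recovered within ±20% on average."""
        estimates = []
        for seed in range(60):
            df = ri_dataset(seed=seed, beta=-5.0)
            X = np.column_stack([np.ones(len(df)), df["so_density"]])
            fit = _fit_gaussian_ri(df["outcome"].to_numpy(), X, df["participant"].to_numpy())
            estimates.append(fit["beta"][1])
        assert abs(np.mean(estimates) - (-5.0)) < 1.0

    def test_null_slopes_rarely_significant(self):
        """With all β = 0, every |z| < 1.96 in at least 90% of seeds."""
        clean = 0
        for seed in range(100):
            df = ri_dataset(seed=seed)
            X = np.column_stack([np.ones(len(df)), df["so_density"]])
            fit = _fit_gaussian_ri(df["outcome"].to_numpy(), X, df["participant"].to_numpy())
            z = fit["beta"][1] / fit["se"][1]
            clean += abs(z) < 1.96
        assert clean >= 90

    def test_zero_between_variance_hits_boundary(self):
        boundary = 0
        for seed in range(20):
            df = simulate_behavior(
                BehaviorSimSpec(17, 11, var_between=0.0, var_within=100.0, seed=seed)
            )
            fit = _fit_gaussian_ri(
                df["outcome"].to_numpy(), np.ones((len(df), 1)), df["participant"].to_numpy()
            )
            boundary += fit["var_between"] < 1.0
        assert boundary > 10

    def test_standardized_and_raw_z_agree(self):
        """z statistics are invariant to z-scoring outcome and predictors."""
        df = ri_dataset(seed=5, beta=-3.0)
        y = df["outcome"].to_numpy()
        x = df["so_density"].to_numpy()
        g = df["participant"].to_numpy()
        raw = _fit_gaussian_ri(y, np.column_stack([np.ones_like(x), x]), g)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        std = _fit_gaussian_ri(ys, np.column_stack([np.ones_like(xs), xs]), g)
        z_raw = raw["beta"][1] / raw["se"][1]
        z_std = std["beta"][1] / std["se"][1]
        assert z_raw == pytest.approx(z_std, abs=1e-6)

    def test_model_result_metadata(self):
        df = ri_dataset(seed=1)
        res = fit_glmm(df, "outcome", ["so_density"])
        assert res.family == "gaussian"
        assert res.icc == pytest.approx(
            res.var_between / (res.var_between + res.var_within)
        )
        assert ((res.fixed_effects["p"] >= 0) & (res.fixed_effects["p"] <= 1)).all()
        assert list(res.type3["term"]) == ["so_density"]


class TestZeroInflatedBeta:
    def make(self, seed=7):
        rng = np.random.default_rng(seed)
        df = simulate_behavior(
            BehaviorSimSpec(
                17, 11, beta0=-2.7, var_between=0.21, var_within=50.0,
                family="beta", zero_inflation_prob=0.3, seed=seed,
            )
        )
        df["x"] = rng.normal(0, 1, len(df))
        return df

    def test_latent_icc_and_components(self):
        df = self.make()
        res = fit_glmm(df, "outcome", ["x"], family="beta", zero_inflated=True)
        assert res.var_within is None
        assert 0.0 <= res.icc <= 1.0
        assert res.icc == pytest.approx(res.var_between / (res.var_between + 1.0))
        assert 0.2 < res.extra["zero_prob"] < 0.45

    def test_boundary_outcomes_require_zero_inflation(self):
        df = self.make()
        with pytest.raises(ValueError, match="zero_inflated"):
            fit_glmm(df, "outcome", ["x"], family="beta", zero_inflated=False)

    def test_agrees_with_glmmtmb_oracle(self, tmp_path):
        """Fixed effects and dispersion match R glmmTMB on the same data."""
        df = self.make(seed=42)
        res = fit_glmm(df, "outcome", ["x"], family="beta", zero_inflated=True)
        csv = tmp_path / "zib.csv"
        df.rename(columns={"outcome": "y"}).to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(y ~ 1 + x + (1|participant), family=beta_family(),
                         ziformula=~1, data=d)
            co <- summary(m)$coefficients$cond
            cat(co[,1], co[,2], VarCorr(m)$cond$participant[1,1], sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1, vb = map(float, out.stdout.split())
        est = res.fixed_effects["estimate"].to_numpy()
        se = res.fixed_effects["se"].to_numpy()
        assert est[0] == pytest.approx(b0, abs=0.02)
        assert est[1] == pytest.approx(b1, abs=0.02)
        assert se[0] == pytest.approx(se0, rel=0.1)
        assert se[1] == pytest.approx(se1, rel=0.1)
        assert res.var_between == pytest.approx(vb, abs=0.05)


class TestBootstrapAndPower:
    def test_bootstrap_ci_deterministic_and_sane(self):
        df = ri_dataset(seed=2)
        res = fit_glmm(df, "outcome", ["so_density"])
        a = bootstrap_icc_ci(res, n_boot=200, seed=9)
        b = bootstrap_icc_ci(res, n_boot=200, seed=9)
        assert a == b
        assert 0.0 <= a[0] < res.icc < a[1] <= 1.0

    def test_vanishing_within_variance_concentrates_near_one(self):
        df = ri_dataset(seed=4, vb=2000.0, vw=0.5)
        res = fit_glmm(df, "outcome", ["so_density"])
        lo, hi = bootstrap_icc_ci(res, n_boot=200, seed=1)
        assert lo > 0.99

    def test_power_curve_shape(self):
        """Size ≈ α at β=0, monotone in |β| up to MC error, → 1 for large β."""
        pw = simulate_power([0.0, -2.0, -5.0], n_sims=200, seed=6)
        power = pw.set_index("effect")["power"]
        mc = 3 * np.sqrt(0.25 / 200)
        assert power[0.0] < 0.05 + mc
        assert power[-5.0] >= power[-2.0] - mc >= power[0.0] - 2 * mc
        assert power[-5.0] > 0.9

    def test_power_requires_enough_sims(self):
        with pytest.raises(ValueError):
            simulate_power([1.0], n_sims=10)


def test_robust_z_flags_isolated_high_density():
    vals = np.r_[np.random.default_rng(0).normal(4.2, 1.0, 50), 40.0]
    flags = robust_z_outliers(vals)
    assert flags[-1] and flags[:-1].sum() == 0
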