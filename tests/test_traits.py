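"""Trial mixed models: razor, BLUEs, variance components, H2, LSD letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxemap import simulate as sim
from gxemap import traits
from gxemap.simulate import TrialData


def _balanced_trial(n_lines=40, envs=(2.0, -1.0, 0.5, -1.5), reps=2,
                    sigma_g=2.0, sigma_ge=0.0, resid_sd=1.0, seed=0,
                    mu=10.0):
    """Hand-built balanced complete trial: one block per replicate, no
    block/rep effects, optional iid GxE, homoscedastic residuals."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, sigma_g, n_lines)
    ge = rng.normal(0, sigma_ge, (n_lines, len(envs)))
    rows = []
    for j, h in enumerate(envs):
        for r in range(reps):
            for i in range(n_lines):
                val = mu + g[i] + h + ge[i, j] + rng.normal(0, resid_sd)
                rows.append((f"L{i:03d}", f"E{j}", f"rep{r+1}",
                             f"E{j}.rep{r+1}.b1", False, val))
    plots = pd.DataFrame(rows, columns=["line", "env", "rep", "block",
                                        "is_check", "value"])
    truth = {"mu": mu, "g": g, "h": np.array(envs), "ge": ge}
    return TrialData(plots=plots, truth=truth)


class TestEnvModel:
    def test_noiseless_blues_exact(self):
        t = _balanced_trial(n_lines=12, resid_sd=1e-9, sigma_g=1.5, seed=1)
        fit = traits.fit_env_model(t, "E0", genotype_fixed=True)
        blues = traits.extract_blues(fit)
        expected = t.truth["mu"] + t.truth["g"] + t.truth["h"][0]
        assert np.allclose(blues.sort_index().to_numpy(), expected, atol=1e-5)

    def test_reml_matches_anova_closed_form(self):
        # balanced two-replicate single environment: REML equals the
        # unstructured-covariance moment estimators (cross-rep covariance
        # and per-rep excess variances)
        t = _balanced_trial(n_lines=300, envs=(0.0,), sigma_g=2.0,
                            resid_sd=1.0, seed=2)
        fit = traits.fit_env_model(t, "E0", genotype_fixed=False)
        df = t.plots
        wide = df.pivot_table(index="line", columns="rep", values="value")
        S = np.cov(wide.to_numpy().T, ddof=1)
        sg_mom = S[0, 1]
        assert fit.variances["genotype"] == pytest.approx(sg_mom, rel=0.05)
        for m, rep in enumerate(fit.resid_group_labels):
            j = list(wide.columns).index(rep)
            assert fit.resid_variances[m] == pytest.approx(S[j, j] - sg_mom, rel=0.12)

    def test_heteroscedastic_replicates_recovered(self):
        rng = np.random.default_rng(13)
        n = 500
        g = rng.normal(0, 2, n)
        rows = []
        for r, sd in enumerate([2.0, 1.0]):
            for i in range(n):
                rows.append((f"L{i}", "E0", f"rep{r+1}", f"b{r+1}", False,
                             g[i] + rng.normal(0, sd)))
        t = TrialData(plots=pd.DataFrame(
            rows, columns=["line", "env", "rep", "block", "is_check", "value"]))
        fit = traits.fit_env_model(t, "E0", genotype_fixed=False)
        ratio = fit.resid_variances[0] / fit.resid_variances[1]
        assert ratio == pytest.approx(4.0, rel=0.30)


class TestJointModel:
    def test_blues_equal_two_way_least_squares_on_balanced_data(self):
        # with homogeneous residuals and a balanced layout GLS reduces to OLS
        t = _balanced_trial(n_lines=25, resid_sd=0.01, seed=4)
        jf = traits.fit_joint_model(t, genotype_fixed=True)
        df = t.plots
        # OLS oracle: line one-hot + sum-zero env/rep contrasts
        lines = sorted(df["line"].unique())
        line_mat = pd.get_dummies(df["line"]).reindex(columns=lines).to_numpy(float)
        env = pd.get_dummies(df["env"]).to_numpy(float)
        env_sz = env[:, :-1] - env[:, -1:]
        rep = pd.get_dummies(df["rep"]).to_numpy(float)
        rep_sz = rep[:, :1] - rep[:, 1:2]
        X = np.hstack([line_mat, env_sz, rep_sz])
        coef, *_ = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)
        # agreement at the (small) noise scale: GLS weights are estimated
        assert np.allclose(jf.blues.reindex(lines).to_numpy(), coef[:len(lines)],
                           atol=5e-3)

    def test_zero_gxe_estimated_near_zero(self):
        t = _balanced_trial(n_lines=100, sigma_g=2.0, sigma_ge=0.0, seed=5)
        jf = traits.fit_joint_model(t)
        assert jf.sigma_ge2 < jf.sigma_g2 / 20

    def test_shift_invariance_of_variances_and_blue_order(self):
        t = _balanced_trial(n_lines=30, sigma_ge=0.8, seed=6)
        jf1 = traits.fit_joint_model(t)
        shifted = TrialData(plots=t.plots.assign(value=t.plots["value"] + 100.0))
        jf2 = traits.fit_joint_model(shifted)
        assert jf1.sigma_g2 == pytest.approx(jf2.sigma_g2, rel=1e-3)
        assert jf1.sigma_ge2 == pytest.approx(jf2.sigma_ge2, rel=1e-2, abs=1e-4)
        b1 = traits.fit_joint_model(t, genotype_fixed=True).blues
        b2 = traits.fit_joint_model(shifted, genotype_fixed=True).blues
        assert (b1.sort_values().index == b2.sort_values().index).all()

    def test_ratio_recomputed_from_components(self):
        t = _balanced_trial(n_lines=60, sigma_ge=1.0, seed=7)
        jf = traits.fit_joint_model(t)
        assert jf.ratio == jf.sigma_ge2 / jf.sigma_g2

    def test_single_environment_rejected(self):
        t = _balanced_trial(envs=(0.0,))
        with pytest.raises(ValueError, match="two environments"):
            traits.fit_joint_model(t)


class TestCullisH2:
    def test_zero_genetic_variance_convention(self):
        jf = traits.JointFit(
            mu=0, lines=[], environments=[], blues=None,
            env_effects=pd.Series(dtype=float), sigma_g2=0.0, sigma_ge2=1.0,
            resid_variances=pd.Series(dtype=float), genotype_fixed=False,
        )
        assert traits.cullis_h2(jf) == 0.0

    def test_vanishing_residual_gives_h2_near_one(self):
        t = _balanced_trial(n_lines=40, sigma_g=2.0, sigma_ge=0.0,
                            resid_sd=0.05, seed=8)
        jf = traits.fit_joint_model(t)
        assert jf.h2 > 0.99

    def test_blue_fit_rejected(self):
        t = _balanced_trial(n_lines=15, seed=9)
        jf = traits.fit_joint_model(t, genotype_fixed=True)
        with pytest.raises(ValueError, match="random"):
            traits.cullis_h2(jf)


class TestRazor:
    def test_gross_outlier_removed(self, population, env_specs):
        t = sim.simulate_trial(population, [], env_specs, sigma_g=2.0, seed=10)
        bad = t.plots.index[100]
        t.plots.loc[bad, "value"] += 10 * env_specs[0].resid_sd * 3
        out = traits.razor_outliers(t, threshold=2.8)
        assert len(out.plots) < len(t.plots)
        removed = t.plots.loc[~t.plots.index.isin(out.plots.index)]
        assert bad in set(t.plots.index) - set(out.plots.index) or \
            not (out.plots[["line", "env", "rep", "block"]].eq(
                t.plots.loc[bad, ["line", "env", "rep", "block"]]).all(axis=1)).any()

    def test_infinite_threshold_identity(self, population, env_specs):
        t = sim.simulate_trial(population, [], env_specs, seed=11)
        out = traits.razor_outliers(t, threshold=np.inf)
        assert len(out.plots) == len(t.plots)

    def test_clean_data_removal_near_normal_tail(self, population, env_specs):
        t = sim.simulate_trial(population, [], env_specs, sigma_g=2.0,
                               sigma_ge=1.0, seed=12)
        out = traits.razor_outliers(t, threshold=2.8)
        frac = 1 - len(out.plots) / len(t.plots)
        # two-sided normal tail at 2.8 is ~0.51%
        assert 0.0 < frac < 0.015


class TestLsd:
    def test_identical_means_one_letter(self):
        means = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        letters = traits.lsd_groups(means, mse=1.0, n=4, df_resid=20)
        assert set(letters) == {"a"}

    def test_gross_separation_distinct_letters(self):
        lsd = stats.t.ppf(0.975, 20) * np.sqrt(2 * 1.0 / 4)
        means = pd.Series([0.0, 10 * lsd], index=["lo", "hi"])
        letters = traits.lsd_groups(means, mse=1.0, n=4, df_resid=20)
        assert letters["lo"] != letters["hi"]

    def test_grouping_matches_all_pairs_t_tests(self):
        means = pd.Series([10.0, 9.2, 8.9, 5.0], index=list("wxyz"))
        mse, n, dfres = 0.8, 4, 24
        letters = traits.lsd_groups(means, mse, n, dfres)
        lsd = stats.t.ppf(0.975, dfres) * np.sqrt(2 * mse / n)
        for a in means.index:
            for b in means.index:
                if a >= b:
                    continue
                nonsig = abs(means[a] - means[b]) < lsd
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == nonsig, (a, b)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            traits.lsd_groups(pd.Series([1.0, 2.0]), 1.0, n=1, df_resid=5)


class TestSummaryTable:
    def test_ratio_column_recomputed(self):
        table = traits.summary_table({
            "A": {"sigma_g2": 2.0, "sigma_ge2": 1.0},
            "B": {"sigma_g2": 4.0, "sigma_ge2": 1.0},
        })
        assert table.loc["A", "Ratio"] == 0.5
        assert table.loc["B", "Ratio"] == 0.25

    def test_zero_genetic_variance_rejected(self):
        with pytest.raises(ValueError):
            traits.variance_ratio(0.0, 1.0)
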