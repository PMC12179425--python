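"""GEE estimating equations, sandwich variance, screening, residualization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize

from twinace import SimSpec, infant_cohort_spec, fit_gee, residualize, simulate_dataset
from twinace.gee import pgs_association, screen_covariates, to_long
from twinace.simulate import CovariateSpec, simulate_pgs_columns


def singleton_cluster_data(n=60, seed=0):
    """Wide pair table where twin 2 is entirely absent: clusters of size 1."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    return pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(n)],
        "zygosity": "MZ",
        "y_t1": y, "y_t2": np.nan,
        "x_t1": x, "x_t2": np.nan,
    })


class TestFitGee:
    def test_singleton_clusters_reduce_to_ols_hc0(self):
        """With clusters of size 1 the GEE is OLS and the sandwich is HC0."""
        df = singleton_cluster_data()
        fit = fit_gee(df, "y", ["x"], working_correlation="independence",
                      standardize=False)
        long = to_long(df, ["y", "x"]).dropna()
        X = sm.add_constant(long["x"])
        ols = sm.OLS(long["y"], X).fit(cov_type="HC0")
        assert fit.coefficients["intercept"] == pytest.approx(ols.params.iloc[0], abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(ols.params.iloc[1], abs=1e-10)
        assert fit.robust_se["intercept"] == pytest.approx(ols.bse.iloc[0], abs=1e-8)
        assert fit.robust_se["x"] == pytest.approx(ols.bse.iloc[1], abs=1e-8)

    def test_hand_dataset_matches_bruteforce_root_of_estimating_equations(self):
        """3 clusters, 6 rows: solve sum_i X_i'(y_i - X_i b) = 0 generically."""
        df = pd.DataFrame({
            "pair_id": ["a", "b", "c"],
            "zygosity": "MZ",
            "y_t1": [1.0, 2.0, 4.0], "y_t2": [1.5, 2.5, 3.0],
            "x_t1": [0.0, 1.0, 2.0], "x_t2": [0.5, 1.5, 2.5],
        })
        long = to_long(df, ["y", "x"])
        X = np.column_stack([np.ones(6), long["x"]])
        y = long["y"].to_numpy()

        def score(beta):
            return X.T @ (y - X @ beta)

        brute = optimize.root(score, x0=np.zeros(2), tol=1e-14).x
        fit = fit_gee(df, "y", ["x"], working_correlation="independence",
                      standardize=False)
        assert fit.coefficients["intercept"] == pytest.approx(brute[0], abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(brute[1], abs=1e-8)

    @pytest.mark.parametrize("working", ["independence", "exchangeable"])
    def test_matches_statsmodels_gee(self, working, study_dataset):
        """Independent oracle: statsmodels GEE on the same standardized data."""
        df = simulate_dataset(infant_cohort_spec(seed=42, missing_rate=0.0))
        covs = ["age_days", "term_age", "income"]
        fit = fit_gee(df, "motor", covs, working_correlation=working)
        long = to_long(df, ["motor", *covs]).dropna()
        yz = (long["motor"] - long["motor"].mean()) / long["motor"].std()
        Xz = long[covs].apply(lambda c: (c - c.mean()) / c.std())
        struct = (sm.cov_struct.Independence() if working == "independence"
                  else sm.cov_struct.Exchangeable())
        oracle = sm.GEE(yz, sm.add_constant(Xz), groups=long["pair_id"],
                        family=sm.families.Gaussian(), cov_struct=struct).fit()
        ours = np.array([fit.coefficients[k] for k in fit.predictors])
        np.testing.assert_allclose(ours, oracle.params.to_numpy(), atol=1e-8)
        ses = np.array([fit.robust_se[k] for k in fit.predictors])
        np.testing.assert_allclose(ses, oracle.bse.to_numpy(), atol=1e-8)

    def test_recovers_generating_age_effect(self):
        spec = infant_cohort_spec(seed=77, n_mz=2000, n_dz=1600, missing_rate=0.0)
        df = simulate_dataset(spec)
        fit = fit_gee(df, "motor", ["age_days", "term_age", "sex", "income"])
        assert fit.coefficients["age_days"] == pytest.approx(0.28, abs=0.05)
        assert fit.ci_low["age_days"] > 0  # CI excludes zero

    def test_ci_identity_and_sandwich_psd(self, study_dataset):
        df = simulate_dataset(infant_cohort_spec(seed=3, missing_rate=0.01))
        fit = fit_gee(df, "social_communication", ["age_days", "income"])
        for k in fit.predictors:
            assert fit.ci_low[k] == pytest.approx(
                fit.coefficients[k] - 1.96 * fit.robust_se[k], abs=1e-9
            )
            assert fit.ci_high[k] == pytest.approx(
                fit.coefficients[k] + 1.96 * fit.robust_se[k], abs=1e-9
            )
        eig = np.linalg.eigvalsh(fit.robust_cov)
        assert eig.min() >= -1e-12
        assert fit.n_clusters <= fit.n_individuals

    def test_exchangeable_agrees_with_independence_on_exchangeable_data(self):
        df = simulate_dataset(infant_cohort_spec(seed=8, missing_rate=0.0))
        covs = ["age_days", "income"]
        b_ind = fit_gee(df, "motor", covs, "independence").coefficients
        b_exc = fit_gee(df, "motor", covs, "exchangeable").coefficients
        for k in b_ind:
            assert b_ind[k] == pytest.approx(b_exc[k], abs=0.02)

    def test_rank_deficiency_names_columns(self, study_dataset):
        df = study_dataset.copy()
        df["dup_t1"] = df["motor_t1"]
        df["dup_t2"] = df["motor_t2"]
        with pytest.raises(ValueError, match="collinear"):
            fit_gee(df, "social_communication", ["motor", "dup"])
        df["const_t1"] = 1.0
        df["const_t2"] = 1.0
        with pytest.raises(ValueError, match="collinear"):
            fit_gee(df, "social_communication", ["const"])


class TestScreening:
    def test_retains_truly_associated_covariates(self):
        """Decision logic: only covariates with real effects survive."""
        covs = (
            CovariateSpec(name="age_days", mean=167.3, sd=8.9, level="pair",
                          effects={"motor": 0.28, "social_communication": 0.15}),
            CovariateSpec(name="term_age", mean=259.2, sd=7.8, level="pair",
                          effects={"motor": 0.17, "social_communication": 0.11}),
            CovariateSpec(name="income", kind="ordinal",
                          levels=tuple(range(1, 12)), level="pair",
                          effects={"motor": -0.19, "social_communication": -0.11}),
            CovariateSpec(name="sex", kind="binary", p=0.5, level="pair"),
            CovariateSpec(name="parental_age", mean=35.3, sd=4.8, level="pair"),
        )
        spec = SimSpec(
            n_mz=1200, n_dz=1000, traits=("motor", "social_communication"),
            means=(10.27, 34.22), total_var=(1.05**2, 1.65**2),
            ace=((0.21, 0.67, 0.12), (0.12, 0.78, 0.10)),
            r_a=-0.39, r_c=0.45, r_e=0.32, covariates=covs, seed=21,
        )
        df = simulate_dataset(spec)
        result = screen_covariates(
            df, ["motor", "social_communication"],
            ["age_days", "term_age", "income", "sex", "parental_age"],
        )
        assert set(result.retained) == {"age_days", "term_age", "income"}

    def test_marginal_mode_runs(self, study_dataset):
        df = simulate_dataset(infant_cohort_spec(seed=4, missing_rate=0.0))
        result = screen_covariates(df, ["motor"], ["age_days", "sex"],
                                   mode="marginal")
        assert set(result.p_values["motor"]) == {"age_days", "sex"}


class TestResidualize:
    def test_residuals_centred_and_orthogonal(self):
        df = simulate_dataset(infant_cohort_spec(seed=31, missing_rate=0.0))
        out = residualize(df, "motor", ["age_days", "term_age", "income"])
        long = to_long(out, ["motor", "age_days", "term_age", "income"]).dropna()
        r = long["motor"].to_numpy()
        assert abs(r.mean()) < 1e-9
        for c in ("age_days", "term_age", "income"):
            x = long[c].to_numpy()
            assert abs(np.corrcoef(r, x)[0, 1]) < 1e-9

    def test_orthogonal_covariate_leaves_centred_trait(self, study_dataset):
        df = study_dataset.copy()
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(2 * len(df))
        motor = np.concatenate([df["motor_t1"], df["motor_t2"]])
        # project out the trait so the covariate is exactly sample-orthogonal
        X = np.column_stack([np.ones_like(motor), motor])
        noise -= X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        df["noise_t1"] = noise[: len(df)]
        df["noise_t2"] = noise[len(df):]
        out = residualize(df, "motor", ["noise"])
        orig = to_long(df, ["motor"])["motor"]
        res = to_long(out, ["motor"])["motor"]
        np.testing.assert_allclose(res, orig - orig.mean(), atol=1e-9)

    def test_perfect_fit_gives_zero_residuals(self, study_dataset):
        df = study_dataset.copy()
        df["z_t1"] = 2.0 * df["motor_t1"]
        df["z_t2"] = 2.0 * df["motor_t2"]
        out = residualize(df, "z", ["motor"])
        long = to_long(out, ["z"])["z"].dropna()
        np.testing.assert_allclose(long, 0.0, atol=1e-9)

    def test_ace_estimates_invariant_to_covariate_adjustment(self):
        """Generating covariate effects, then residualizing, leaves the ACE
        structure intact within simulation error."""
        from twinace import fit_univariate_ace, standardize

        spec_cov = infant_cohort_spec(seed=55, n_mz=1500, n_dz=1200,
                                   missing_rate=0.0)
        df = simulate_dataset(spec_cov)
        adj = residualize(df, "motor",
                          ["age_days", "term_age", "sex", "parental_age",
                           "parental_education", "income"])
        fit = fit_univariate_ace(adj, "motor", seed=1)
        std = standardize(fit)
        assert std.A[0] == pytest.approx(0.21, abs=0.08)
        assert std.C[0] == pytest.approx(0.67, abs=0.08)


class TestPgsAssociation:
    def test_null_score_slope_near_zero(self, study_dataset):
        df = simulate_pgs_columns(study_dataset, n_scores=1, seed=10)
        fit = pgs_association(df, "motor", "pgs1",
                              [f"pc{i}" for i in range(1, 11)])
        assert abs(fit.coefficients["pgs1"]) < 3 * fit.robust_se["pgs1"]

    def test_recovers_generating_effect(self):
        spec = SimSpec(
            n_mz=3000, n_dz=3000, traits=("y",), means=(0.0,), total_var=(1.0,),
            ace=((0.3, 0.4, 0.3),), seed=12,
        )
        df = simulate_pgs_columns(simulate_dataset(spec), n_scores=1,
                                  effect_sizes=[0.3], seed=13, traits=["y"])
        fit = pgs_association(df, "y", "pgs1", [f"pc{i}" for i in range(1, 11)])
        assert fit.coefficients["pgs1"] == pytest.approx(0.3, abs=0.05)

    def test_score_collinear_with_pc_rejected(self, study_dataset):
        df = simulate_pgs_columns(study_dataset, n_scores=1, seed=10)
        df["pc1_t1"] = df["pgs1_t1"]
        df["pc1_t2"] = df["pgs1_t2"]
        with pytest.raises(ValueError, match="collinear"):
            pgs_association(df, "motor", "pgs1", ["pc1", "pc2"])
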