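"""FIML likelihood, saturated/ACE fits, model comparison, profile CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinace import (
    AceParams,
    SimSpec,
    assumption_tests,
    build_pair_covariance,
    compare_models,
    fiml_minus2ll,
    fit_bivariate_correlated_factors,
    fit_saturated,
    fit_univariate_ace,
    prepare_pairs,
    profile_ci,
    simulate_dataset,
    standardize,
)
from twinace.ace import (
    ASSUMPTION_LADDER,
    BivariateACE,
    BivariateSaturated,
    UnivariateACE,
    UnivariateSaturated,
    _fit_structure,
)

from conftest import study_spec


def pair_frame(rows, traits=("u", "v"), zygosity=None):
    """rows: array (n, 2T) in (t1 traits..., t2 traits...) order."""
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    cols = [f"{t}_t1" for t in traits] + [f"{t}_t2" for t in traits]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "zygosity", zygosity if zygosity is not None else ["MZ"] * n)
    df.insert(0, "pair_id", [f"p{i}" for i in range(n)])
    return df


class TestFimlMinus2LL:
    def test_standard_normal_single_pair(self):
        """One pair at the mean under identity covariance: -2LL = 2 log 2pi."""
        params = AceParams(traits=("y",), means=(0.0,), a2=(0.0,), c2=(0.0,), e2=(1.0,))
        df = pair_frame([[0.0, 0.0]], traits=("y",))
        assert fiml_minus2ll(params, df) == pytest.approx(
            2.0 * np.log(2.0 * np.pi), abs=1e-12
        )

    def test_matches_bruteforce_mvn_density_sum(self, rng):
        """Oracle: per-pair scipy multivariate_normal log-densities."""
        for trial in range(50):
            a1, c1 = rng.uniform(0.05, 0.5, 2)
            a2_, c2_ = rng.uniform(0.05, 0.5, 2)
            params = AceParams(
                traits=("u", "v"),
                means=tuple(rng.normal(0, 2, 2)),
                a2=(a1, a2_), c2=(c1, c2_),
                e2=tuple(rng.uniform(0.2, 1.0, 2)),
                r_a=rng.uniform(-0.9, 0.9), r_c=rng.uniform(-0.9, 0.9),
                r_e=rng.uniform(-0.9, 0.9),
            )
            n = 20
            zyg = np.array(["MZ"] * 10 + ["DZ"] * 10)
            data = rng.normal(0, 1, size=(n, 4))
            # sprinkle missingness to exercise the marginalization path
            mask = rng.random((n, 4)) < 0.15
            mask[mask.all(axis=1)] = False
            data[mask] = np.nan
            keep = ~np.isnan(data).all(axis=1)
            df = pair_frame(data[keep], zygosity=zyg[keep])

            mu = np.concatenate([params.means, params.means])
            covs = {z: build_pair_covariance(params, z) for z in ("MZ", "DZ")}
            expected = 0.0
            for z, row in zip(zyg[keep], data[keep]):
                obs = ~np.isnan(row)
                d = stats.multivariate_normal(
                    mean=mu[obs], cov=covs[z][np.ix_(obs, obs)]
                )
                expected += -2.0 * d.logpdf(row[obs])
            assert fiml_minus2ll(params, df) == pytest.approx(expected, abs=1e-10)

    def test_incomplete_pair_contributes_marginal_density(self):
        params = AceParams(traits=("y",), means=(1.0,), a2=(0.3,), c2=(0.3,), e2=(0.4,))
        complete = pair_frame([[1.2, 0.7]], traits=("y",))
        both = pair_frame([[1.2, 0.7], [2.0, np.nan]], traits=("y",))
        marginal = -2.0 * stats.norm(1.0, 1.0).logpdf(2.0)
        assert fiml_minus2ll(params, both) == pytest.approx(
            fiml_minus2ll(params, complete) + marginal, abs=1e-10
        )

    def test_non_pd_covariance_gives_inf(self):
        from twinace.ace import _minus2ll_moments

        prep = prepare_pairs(pair_frame([[0.0, 0.0]], traits=("y",)), ("y",))
        means = np.zeros((2, 2))
        covs = np.stack([np.array([[1.0, 2.0], [2.0, 1.0]])] * 2)  # indefinite
        assert _minus2ll_moments(means, covs, prep) == np.inf


class TestSaturated:
    def test_parameter_counts(self):
        assert UnivariateSaturated("y").k == 10
        assert BivariateSaturated(("u", "v")).k == 28
        assert UnivariateACE("y").k == 4
        assert BivariateACE(("u", "v")).k == 11

    def test_complete_data_matches_sample_moments(self):
        df = simulate_dataset(study_spec(seed=101))
        fit = fit_saturated(df, ["motor", "social_communication"], seed=1)
        assert fit.converged
        cols = ["motor_t1", "social_communication_t1",
                "motor_t2", "social_communication_t2"]
        for zyg in ("MZ", "DZ"):
            block = df.loc[df["zygosity"] == zyg, cols].to_numpy()
            mu = block.mean(axis=0)
            cov = np.cov(block, rowvar=False, ddof=0)  # ML divide-by-n
            for i, lab in enumerate(fit.structure.labels):
                assert fit.params[f"mean_{zyg}_{lab}"] == pytest.approx(
                    mu[i], abs=1e-6
                )
                assert fit.params[f"cov_{zyg}_{lab}_{lab}"] == pytest.approx(
                    cov[i, i], abs=1e-5
                )

    def test_univariate_complete_data_moments(self):
        spec = SimSpec(n_mz=300, n_dz=200, traits=("y",), means=(5.0,),
                       total_var=(2.0,), ace=((0.4, 0.3, 0.3),), seed=3)
        df = simulate_dataset(spec)
        fit = fit_saturated(df, ["y"], seed=1)
        assert fit.k == 10
        sub = df[df["zygosity"] == "MZ"]
        assert fit.params["mean_MZ_t1"] == pytest.approx(
            sub["y_t1"].mean(), abs=1e-6
        )

    def test_assumption_ladder_df_and_null_behaviour(self):
        df = simulate_dataset(study_spec(seed=5))
        comps = assumption_tests(df, "motor", seed=1)
        assert [c.delta_df for c in comps] == [2, 3, 5, 6]
        for c in comps:
            assert c.delta_ll >= 0
            assert 0 <= c.p_value <= 1

    def test_shifted_twin2_mean_rejects_equality(self):
        spec = SimSpec(n_mz=2000, n_dz=2000, traits=("y",), means=(0.0,),
                       total_var=(1.0,), ace=((0.3, 0.4, 0.3),), seed=9)
        df = simulate_dataset(spec)
        df["y_t2"] += 1.0  # +1 SD shift on twin 2
        with pytest.warns(UserWarning, match="assumption"):
            comps = assumption_tests(df, "y", seed=1)
        assert comps[0].p_value < 1e-6


class TestAceFits:
    def test_univariate_recovery(self):
        spec = SimSpec(n_mz=3000, n_dz=3000, traits=("y",), means=(2.0,),
                       total_var=(1.5,), ace=((0.5, 0.3, 0.2),), seed=17)
        fit = fit_univariate_ace(simulate_dataset(spec), "y", seed=1)
        assert fit.converged
        std = standardize(fit)
        assert std.A[0] == pytest.approx(0.5, abs=0.05)
        assert std.C[0] == pytest.approx(0.3, abs=0.05)
        assert fit.params["mean_y"] == pytest.approx(2.0, abs=0.05)

    def test_no_familial_resemblance_boundary(self):
        spec = SimSpec(n_mz=2000, n_dz=2000, traits=("y",), means=(0.0,),
                       total_var=(1.0,), ace=((0.0001, 0.0001, 0.9998),), seed=23)
        fit = fit_univariate_ace(simulate_dataset(spec), "y", seed=1)
        std = standardize(fit)
        assert std.A[0] == pytest.approx(0.0, abs=0.05)
        assert std.C[0] == pytest.approx(0.0, abs=0.05)

    def test_mz_only_not_identified(self):
        spec = SimSpec(n_mz=100, n_dz=0, traits=("y",), means=(0.0,),
                       total_var=(1.0,), ace=((0.4, 0.3, 0.3),), seed=2)
        with pytest.raises(ValueError, match="both zygosities"):
            fit_univariate_ace(simulate_dataset(spec), "y")

    def test_bivariate_independent_traits_near_zero_correlations(self):
        spec = SimSpec(
            n_mz=3000, n_dz=3000, traits=("u", "v"), means=(0.0, 0.0),
            total_var=(1.0, 1.0), ace=((0.4, 0.3, 0.3), (0.4, 0.3, 0.3)),
            r_a=0.0, r_c=0.0, r_e=0.0, seed=29,
        )
        fit = fit_bivariate_correlated_factors(simulate_dataset(spec),
                                               ("u", "v"), seed=1)
        std = standardize(fit)
        assert abs(std.r_a) < 0.15
        assert abs(std.r_c) < 0.15
        assert abs(std.r_e) < 0.1

    def test_nesting_monotonicity_across_model_ladder(self):
        """Every constrained model has -2LL >= its parent's."""
        df = simulate_dataset(study_spec(seed=41, missing_rate=0.02))
        prep2 = prepare_pairs(df, ("motor", "social_communication"))
        sat2 = fit_saturated(prep2, ["motor", "social_communication"], seed=1)
        biv = fit_bivariate_correlated_factors(prep2, ("motor", "social_communication"), seed=1)
        assert biv.minus2ll >= sat2.minus2ll - 1e-6
        biv_rc0 = fit_bivariate_correlated_factors(
            prep2, ("motor", "social_communication"), seed=1, fixed={"r_c": 0.0}
        )
        assert biv_rc0.minus2ll >= biv.minus2ll - 1e-6

        prep1 = prepare_pairs(df, ("motor",))
        sat1 = fit_saturated(prep1, ["motor"], seed=1)
        for _, constraints in ASSUMPTION_LADDER:
            sub = _fit_structure(UnivariateSaturated("motor", **constraints),
                                 prep1, seed=1)
            assert sub.minus2ll >= sat1.minus2ll - 1e-6
        uni = fit_univariate_ace(prep1, "motor", seed=1)
        assert uni.minus2ll >= sat1.minus2ll - 1e-6

    def test_scale_invariance(self):
        """x10 rescaling leaves standardized estimates and LRTs unchanged."""
        df = simulate_dataset(study_spec(seed=3))
        traits = ("motor", "social_communication")
        scaled = df.copy()
        for c in scaled.columns[2:]:
            scaled[c] = scaled[c] * 10.0
        f1 = fit_bivariate_correlated_factors(df, traits, seed=1)
        f2 = fit_bivariate_correlated_factors(scaled, traits, seed=1)
        s1, s2 = standardize(f1), standardize(f2)
        np.testing.assert_allclose(s1.A, s2.A, atol=1e-6)
        np.testing.assert_allclose(s1.C, s2.C, atol=1e-6)
        assert s1.r_c == pytest.approx(s2.r_c, abs=1e-6)
        d1 = compare_models(fit_saturated(df, list(traits), seed=1), f1)
        d2 = compare_models(fit_saturated(scaled, list(traits), seed=1), f2)
        assert d1.delta_ll == pytest.approx(d2.delta_ll, abs=1e-6)

    def test_missing_data_df_bookkeeping(self):
        df = simulate_dataset(study_spec(seed=61, missing_rate=0.03))
        fit = fit_bivariate_correlated_factors(df, ("motor", "social_communication"), seed=1)
        cells = df[["motor_t1", "motor_t2", "social_communication_t1",
                    "social_communication_t2"]].notna().to_numpy().sum()
        assert fit.n_obs == cells
        assert fit.df == cells - 11


class TestModelComparison:
    def test_information_criteria_identity(self):
        df = simulate_dataset(study_spec(seed=71))
        fit = fit_bivariate_correlated_factors(df, ("motor", "social_communication"), seed=1)
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.k, abs=1e-9)
        assert fit.bic == pytest.approx(
            fit.minus2ll + fit.k * np.log(fit.n_pairs), abs=1e-9
        )

    def test_identical_fits_zero_delta(self):
        df = simulate_dataset(study_spec(seed=73))
        sat = fit_saturated(df, ["motor", "social_communication"], seed=1)
        biv = fit_bivariate_correlated_factors(df, ("motor", "social_communication"), seed=1)
        comp = compare_models(sat, biv)
        assert comp.delta_df == 17
        assert comp.delta_ll >= 0

    def test_non_nested_rejected(self):
        df = simulate_dataset(study_spec(seed=73))
        sat = fit_saturated(df, ["motor", "social_communication"], seed=1)
        with pytest.raises(ValueError, match="not nested"):
            compare_models(sat, sat)


class TestProfileCI:
    def test_mean_parameter_ci_symmetric_quadratic_limit(self):
        spec = SimSpec(n_mz=500, n_dz=400, traits=("y",), means=(3.0,),
                       total_var=(1.0,), ace=((0.4, 0.3, 0.3),), seed=83)
        fit = fit_univariate_ace(simulate_dataset(spec), "y", seed=1)
        ci = profile_ci(fit, "mean_y")
        mid = fit.params["mean_y"]
        assert not ci.low_at_bound and not ci.high_at_bound
        assert (mid - ci.low) == pytest.approx(ci.high - mid, rel=0.05)

    def test_ci_width_shrinks_like_root_n(self):
        widths = []
        for n in (400, 1600):
            spec = SimSpec(n_mz=n, n_dz=n, traits=("y",), means=(0.0,),
                           total_var=(1.0,), ace=((0.4, 0.3, 0.3),), seed=97)
            fit = fit_univariate_ace(simulate_dataset(spec), "y", seed=1)
            ci = profile_ci(fit, "A_y")
            widths.append(ci.high - ci.low)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)

    def test_genetic_correlation_lower_bound_pins_at_minus_one(self):
        """At the study design size the rA profile often runs into -1."""
        hits = 0
        for seed in (1, 2, 3, 4, 5):
            df = simulate_dataset(study_spec(seed=seed))
            fit = fit_bivariate_correlated_factors(
                df, ("motor", "social_communication"), seed=seed
            )
            ci = profile_ci(fit, "r_a")
            assert -1.0 <= ci.low <= ci.high <= 1.0
            if ci.low_at_bound and ci.low == -1.0:
                hits += 1
        assert hits >= 1
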