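"""End-to-end estimation: data preparation, regressions, grid estimates,
pooling, contrasts, and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from copstrat.estimator import (
    COVARIATE_COLS,
    bootstrap_cis,
    estimate_cate,
    fit_biomarker_regressions,
    interaction_contrast,
    pool_trials,
    prepare_dataset,
)
from copstrat.sir import SIRConfig
from copstrat.synthetic import GeneratorConfig, generate_trial

SMALL_SIR = SIRConfig(n_proposal=10000, n_resample=300, seed=77)


def _result(grid, est, endpoint="primary", rho=0.8, n=100):
    from copstrat.estimator import CATEResult
    return CATEResult(endpoint=endpoint, horizon=2.0, rho_eps=rho,
                      grid=np.asarray(grid, float),
                      estimate=np.asarray(est, float), n=n)


class TestPrepareDataset:
    def test_two_sided_trim_of_thousand_rows(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({c: rng.normal(size=1000) for c in COVARIATE_COLS})
        df["subject_id"] = np.arange(1000)
        df["trial"] = "T"
        df["arm"] = rng.binomial(1, 0.5, 1000)
        df["time_years"] = rng.exponential(1, 1000)
        df["event_type"] = 0
        df["delta_egfr_pct"] = rng.normal(0, 12, 1000)
        out, report = prepare_dataset(df)
        assert report["n_final"] == 990
        assert report["n_trimmed"] == 10

    def test_missing_value_row_dropped_and_counted(self):
        ds, _ = generate_trial(GeneratorConfig(n_per_arm=200, seed=1))
        ds.loc[3, "age"] = np.nan
        out, report = prepare_dataset(ds)
        assert report["n_dropped_missing"] == 1
        assert 3 not in out["subject_id"].values or ds.loc[3, "subject_id"] not in out["subject_id"].values

    def test_degenerate_biomarker_not_trimmed(self):
        ds, _ = generate_trial(GeneratorConfig(n_per_arm=100, seed=2))
        ds["delta_egfr_pct"] = -5.0
        out, report = prepare_dataset(ds)
        assert report["n_trimmed"] == 0
        assert report["n_final"] == len(ds)

    def test_missing_column_raises_schema_error(self):
        with pytest.raises(ValueError, match="missing required"):
            prepare_dataset(pd.DataFrame({"arm": [0, 1]}))


class TestBiomarkerRegressions:
    def test_slope_recovery_on_generator(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        bm = fit_biomarker_regressions(df)
        cfg = GeneratorConfig()
        # MC standard error of an OLS slope ~ sd_resid / (sd_x * sqrt(n))
        n = (df["arm"] == 1).sum()
        for col, sd_x in (("egfr0", 22.3), ("age", 9.8)):
            se = bm.sd1 / (sd_x * np.sqrt(n))
            assert abs(bm.beta1[col] - cfg.slopes1[col]) < 2.5 * se
        for col in ("egfr0", "age"):
            se = bm.sd0 / ({"egfr0": 22.3, "age": 9.8}[col] * np.sqrt(n))
            assert abs(bm.beta0[col] - cfg.slopes0[col]) < 2.5 * se

    def test_residuals_centered(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        bm = fit_biomarker_regressions(df)
        assert abs(bm.resid0.mean()) < 1e-10
        assert abs(bm.resid1.mean()) < 1e-10

    def test_arm_swap_permutes_coefficients(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        swapped = df.assign(arm=1 - df["arm"])
        bm = fit_biomarker_regressions(df)
        bm_sw = fit_biomarker_regressions(swapped)
        pd.testing.assert_series_equal(bm.beta0.sort_index(),
                                       bm_sw.beta1.sort_index())

    def test_collinear_covariates_rejected(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        df = df.assign(age2=df["age"])
        with pytest.raises(ValueError, match="collinear"):
            fit_biomarker_regressions(df, covariate_cols=("age", "age2"))


class TestEstimateCate:
    def test_rho_one_no_covariates_matches_plug_in(self, default_trial):
        """With rho_eps = 1 and intercept-only regressions the estimate must
        equal the direct substitution w0 = F0^-1(F1(w1))."""
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        from copstrat.distributions import johnson_cdf, johnson_quantile
        from copstrat.hazard import DesignSpec, default_knots, fit_fine_gray, predict_risk

        res = estimate_cate(df, endpoint="primary", k=2.0, rho_eps=1.0,
                            w1_grid=[-15.0, 0.0, 10.0], J=5,
                            sir_config=SMALL_SIR, seed=3, covariate_cols=())
        bm = fit_biomarker_regressions(df, covariate_cols=())
        spline = default_knots(df["delta_egfr_pct"].to_numpy(), 4)
        design = DesignSpec(spline=spline, covariate_cols=())
        fit1 = fit_fine_gray(df[df.arm == 1], design, 1)
        fit0 = fit_fine_gray(df[df.arm == 0], design, 1)
        mu1, mu0 = float(bm.beta1["const"]), float(bm.beta0["const"])
        for gi, w1 in enumerate(res.grid):
            r0 = johnson_quantile(bm.fr0, johnson_cdf(bm.fr1, w1 - mu1))
            direct = (predict_risk(fit0, mu0 + r0, [], 2.0)
                      - predict_risk(fit1, w1, [], 2.0))
            assert res.estimate[gi] == pytest.approx(direct, abs=0.002)

    def test_null_generator_estimates_near_zero(self, null_trial):
        ds, _ = null_trial
        df, _ = prepare_dataset(ds)
        for rho in (0.0, 0.8, 1.0):
            res = estimate_cate(df, endpoint="composite", k=2.0, rho_eps=rho,
                                w1_grid=[-10.0, 0.0, 10.0], J=30,
                                sir_config=SMALL_SIR, seed=4)
            # sanity bound ~ 3x the empirical sampling SD of the estimator
            # at this size; the calibrated SE-based check lives in the
            # acceptance suite
            assert np.all(np.abs(res.estimate) < 0.03)

    def test_rho_out_of_range_rejected(self, default_trial):
        ds, _ = default_trial
        with pytest.raises(ValueError, match="rho_eps"):
            estimate_cate(ds, rho_eps=1.5)

    def test_continuity_in_rho(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        grid = [-20.0, -10.0, 0.0, 10.0]
        curves = []
        for rho in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            res = estimate_cate(df, endpoint="primary", k=2.0, rho_eps=rho,
                                w1_grid=grid, J=40, sir_config=SMALL_SIR, seed=5)
            curves.append(res.estimate)
        diffs = [np.max(np.abs(a - b)) for a, b in zip(curves, curves[1:])]
        assert max(diffs) < 0.05

    def test_composite_close_to_sum_of_causes(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        grid = [-10.0, 0.0]
        parts = {}
        for ep in ("primary", "competing", "composite"):
            parts[ep] = estimate_cate(df, endpoint=ep, k=2.0, rho_eps=0.8,
                                      w1_grid=grid, J=40, sir_config=SMALL_SIR,
                                      seed=6).estimate
        assert np.max(np.abs(parts["composite"]
                             - (parts["primary"] + parts["competing"]))) < 0.01

    def test_deterministic_under_seed(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        kw = dict(endpoint="primary", k=2.0, rho_eps=0.6, w1_grid=[0.0],
                  J=10, sir_config=SMALL_SIR, seed=7)
        a = estimate_cate(df, **kw)
        b = estimate_cate(df, **kw)
        assert np.array_equal(a.estimate, b.estimate)


class TestPooling:
    def test_weighted_average(self):
        a = _result([0.0], [0.01], n=100)
        b = _result([0.0], [0.03], n=100)
        pooled = pool_trials([a, b])
        assert pooled.estimate[0] == pytest.approx(0.02)
        assert sum(pooled.weights.values()) == pytest.approx(1.0)

    def test_single_trial_identity(self):
        a = _result([0.0, 1.0], [0.01, 0.02])
        pooled = pool_trials([a])
        assert np.allclose(pooled.estimate, a.estimate)

    def test_unequal_sizes(self):
        a = _result([0.0], [0.00], n=3000)
        b = _result([0.0], [0.04], n=1000)
        pooled = pool_trials([a, b])
        assert pooled.estimate[0] == pytest.approx(0.01)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            pool_trials([_result([0.0], [0.01]), _result([1.0], [0.01])])


class TestInteractionContrast:
    def test_zero_at_reference(self):
        res = _result([-10.0, 0.0, 10.0], [0.03, 0.01, 0.005])
        c = interaction_contrast(res)
        assert c.estimate[1] == 0.0
        assert c.estimate[0] == pytest.approx(0.02)

    def test_constant_curve_gives_zero_contrast(self):
        res = _result([-10.0, 0.0, 10.0], [0.02, 0.02, 0.02])
        assert np.allclose(interaction_contrast(res).estimate, 0.0)

    def test_larger_declines_larger_benefit_detected(self):
        """Degenerate-coupling generator with identical arm marginals and a
        multiplicative protective effect: absolute risk reduction must grow
        with the acute decline at rho_eps = 1."""
        cfg = GeneratorConfig(
            n_per_arm=8000, rho_true=1.0, seed=31,
            mean_w1=-0.6,
            slopes1={"egfr0": 0.04, "log_upcr": -0.25, "age": -0.015,
                     "sbp": -0.008, "female": 0.3, "diabetes": -0.4},
            resid_shape1=(-0.6, 2.2),
        )
        ds, _ = generate_trial(cfg)
        df, _ = prepare_dataset(ds)
        res = estimate_cate(df, endpoint="primary", k=2.0, rho_eps=1.0,
                            w1_grid=[-20.0, 0.0], J=20,
                            sir_config=SMALL_SIR, seed=8)
        contrast = interaction_contrast(res)
        assert contrast.estimate[0] > 0


class TestBootstrap:
    def test_two_replicates_give_min_max(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        lo, hi, mat, nf = bootstrap_cis(
            df, B=2, seed=9, endpoint="primary", k=2.0, rho_eps=0.8,
            w1_grid=[0.0], J=10, sir_config=SMALL_SIR)
        assert nf == 0
        assert lo[0] == pytest.approx(mat.min(axis=0)[0])
        assert hi[0] == pytest.approx(mat.max(axis=0)[0])

    def test_fixed_seed_reproducible(self, default_trial):
        ds, _ = default_trial
        df, _ = prepare_dataset(ds)
        kw = dict(B=3, seed=10, endpoint="primary", k=2.0, rho_eps=0.8,
                  w1_grid=[0.0], J=10, sir_config=SMALL_SIR)
        lo1, hi1, _, _ = bootstrap_cis(df, **kw)
        lo2, hi2, _, _ = bootstrap_cis(df, **kw)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)
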