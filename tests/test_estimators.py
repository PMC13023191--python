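import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from binmr import estimators as est
from binmr.simulate import SimulationConfig, draw_dataset


def sm_logit(y, *cols):
    X = sm.add_constant(np.column_stack(cols))
    return sm.Logit(y, X).fit(disp=0).params


def sm_ols(y, *cols):
    X = sm.add_constant(np.column_stack(cols))
    return sm.OLS(y, X).fit().params


# ---------------------------------------------------------------------------
# fitting kernels

class TestFitLogistic:
    def test_matches_statsmodels_on_tiny_fixture(self, eight_row):
        Z, y = eight_row
        fit = est.fit_logistic(y, {"Z": Z})
        oracle = sm_logit(y, Z)
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-6)

    def test_matches_statsmodels_on_varied_datasets(self, small_dataset):
        ds = small_dataset
        fit = est.fit_logistic(ds.Y, {"Z": ds.Z, "X": ds.X.astype(float)})
        oracle = sm.Logit(
            ds.Y, sm.add_constant(np.column_stack([ds.Z, ds.X]))
        ).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, oracle.bse, rtol=1e-4)

    def test_perfect_separation_flagged(self):
        Z = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = est.fit_logistic(Z.copy(), {"Z": Z})
        assert not fit.converged

    def test_constant_response_raises(self):
        with pytest.raises(est.DegenerateFitError):
            est.fit_logistic(np.ones(10), {"Z": np.arange(10.0)})

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(0)
        z = rng.integers(0, 2, 100).astype(float)
        y = rng.integers(0, 2, 100).astype(float)
        with pytest.raises(est.RankDeficiencyError):
            est.fit_logistic(y, {"a": z, "b": 2 * z})

    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        n = 100_000
        Z = rng.integers(0, 2, n).astype(float)
        p = 1 / (1 + np.exp(-(0.5 + 1.0 * Z)))
        y = (rng.random(n) < p).astype(float)
        fit = est.fit_logistic(y, {"Z": Z})
        assert abs(fit.coef("const") - 0.5) < 3 * fit.se("const")
        assert abs(fit.coef("Z") - 1.0) < 3 * fit.se("Z")


class TestFitLpm:
    def test_slope_is_group_mean_difference(self):
        Z = np.repeat([0.0, 1.0], 10)
        y = np.r_[np.repeat([0.0, 1.0], [7, 3]), np.repeat([0.0, 1.0], [5, 5])]
        fit = est.fit_lpm(y, {"Z": Z})
        assert fit.coef("Z") == pytest.approx(0.2, abs=1e-12)
        assert fit.coef("const") == pytest.approx(0.3, abs=1e-12)

    def test_identity_case(self):
        Z = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        fit = est.fit_lpm(Z.copy(), {"Z": Z})
        assert fit.coef("Z") == pytest.approx(1.0, abs=1e-12)
        assert fit.coef("const") == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, small_dataset):
        ds = small_dataset
        fit = est.fit_lpm(ds.Y, {"Z": ds.Z, "X": ds.X.astype(float)})
        Xm = np.column_stack([np.ones(ds.n), ds.Z, ds.X])
        oracle = np.linalg.solve(Xm.T @ Xm, Xm.T @ ds.Y)
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# prevalence transformation

@pytest.mark.parametrize(
    "beta, pr, expected",
    [(1.0, 0.5, 0.25), (0.0, 0.3, 0.0), (-2.0, 0.2, -0.32)],
)
def test_transform_coefficient(beta, pr, expected):
    assert est.transform_coefficient(beta, pr) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad_pr", [0.0, 1.0, -0.1, 1.5])
def test_transform_domain(bad_pr):
    with pytest.raises(ValueError):
        est.transform_coefficient(1.0, bad_pr)
    with pytest.raises(ValueError):
        est.inverse_transform(1.0, bad_pr)


def test_inverse_transform_examples():
    assert est.inverse_transform(0.25, 0.5) == pytest.approx(1.0, abs=1e-12)
    assert est.inverse_transform(0.0, 0.123) == 0.0


@settings(derandomize=True, max_examples=200)
@given(
    beta=st.floats(-3, 3, allow_nan=False),
    pr=st.floats(0.05, 0.95, allow_nan=False),
)
def test_transform_roundtrip_identity(beta, pr):
    back = est.inverse_transform(est.transform_coefficient(beta, pr), pr)
    assert back == pytest.approx(beta, abs=1e-12)


# ---------------------------------------------------------------------------
# Wald estimators

class TestWaldEstimators:
    def test_identical_traits_give_unit_ratio(self):
        rng = np.random.default_rng(1)
        Z = rng.integers(0, 2, 200).astype(float)
        X = (rng.random(200) < (0.3 + 0.3 * Z)).astype(float)
        res = est.wald_logistic((Z, X, X))
        assert res.valid
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "method", [est.wald_logistic, est.wald_lpm, est.wald_transformation]
    )
    def test_instrument_recoding_invariance(self, method, small_dataset):
        ds = small_dataset
        a = method((ds.Z, ds.X, ds.Y))
        b = method((1 - ds.Z, ds.X, ds.Y))
        assert a.valid and b.valid
        assert a.estimate == pytest.approx(b.estimate, rel=1e-8, abs=1e-10)

    def test_lpm_hand_computed_example(self):
        # group exposure prevalences 0.3 vs 0.5, outcome 0.45 vs 0.55,
        # overall P(Y)=0.5: linear ratio 0.5, log-odds estimate 0.5/0.25 = 2
        Z = np.repeat([0.0, 1.0], 100)
        X = np.r_[np.repeat([1.0, 0.0], [30, 70]), np.repeat([1.0, 0.0], [50, 50])]
        Y = np.r_[np.repeat([1.0, 0.0], [45, 55]), np.repeat([1.0, 0.0], [55, 45])]
        res = est.wald_lpm((Z, X, Y))
        assert res.valid
        assert res.pr_y == pytest.approx(0.5)
        assert res.estimate == pytest.approx(2.0, abs=1e-9)

    def test_zero_numerator_gives_zero(self):
        # Y independent of Z by construction within each Z group
        Z = np.repeat([0.0, 1.0], 40)
        X = np.r_[np.repeat([1.0, 0.0], [10, 30]), np.repeat([1.0, 0.0], [25, 15])]
        Y = np.tile(np.repeat([1.0, 0.0], [20, 20]), 2)
        res = est.wald_lpm((Z, X, Y))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_transformation_collapse_at_equal_prevalence(self):
        # same sample prevalence of X and Y, different vectors: the two
        # prevalence factors cancel in the linear-scale ratio, which then
        # equals the logistic Wald ratio; the reported log-odds estimate is
        # that ratio back-transformed by the remaining exposure factor
        Z = np.repeat([0.0, 1.0], 50)
        X = np.r_[np.repeat([1.0, 0.0], [15, 35]), np.repeat([1.0, 0.0], [25, 25])]
        Y = np.r_[np.repeat([1.0, 0.0], [12, 38]), np.repeat([1.0, 0.0], [28, 22])]
        assert X.mean() == Y.mean()
        a = est.wald_logistic((Z, X, Y))
        b = est.wald_transformation((Z, X, Y))
        linear_ratio = b.numerator / b.denominator
        assert linear_ratio == pytest.approx(a.estimate, rel=1e-10)
        pr_x = X.mean()
        assert b.estimate == pytest.approx(
            a.estimate / (pr_x * (1 - pr_x)), rel=1e-10)

    def test_transformation_algebraic_reduction(self, small_dataset):
        # est_transformation = est_logistic / (pr_x * (1 - pr_x))
        ds = small_dataset
        a = est.wald_logistic((ds.Z, ds.X, ds.Y))
        b = est.wald_transformation((ds.Z, ds.X, ds.Y))
        pr_x = ds.X.mean()
        assert b.estimate == pytest.approx(a.estimate / (pr_x * (1 - pr_x)), rel=1e-9)

    def test_degenerate_outcome_flagged_not_zero(self):
        Z = np.repeat([0.0, 1.0], 20)
        X = np.tile([0.0, 1.0], 20)
        Y = np.zeros(40)
        res = est.wald_lpm((Z, X, Y))
        assert not res.valid
        assert np.isnan(res.estimate)


# ---------------------------------------------------------------------------
# IV estimators

class TestIVEstimators:
    def test_sem_consistency_without_confounding(self):
        cfg = SimulationConfig(alpha1=0.7, beta1=1.0, cx=0.0, cy=0.0,
                               n=100_000, seed=21)
        ds = draw_dataset(cfg, 0)
        res = est.estimate_sem((ds.Z, ds.X, ds.Y))
        assert res.valid
        se = res.second_stage.se("X")
        assert abs(res.estimate - 1.0) < 3 * se

    def test_sem_null_without_confounding(self):
        cfg = SimulationConfig(alpha1=0.7, beta1=0.0, cx=0.0, cy=0.0,
                               n=100_000, seed=22)
        ds = draw_dataset(cfg, 0)
        res = est.estimate_sem((ds.Z, ds.X, ds.Y))
        assert abs(res.estimate) < 3 * res.second_stage.se("X")

    def test_sem_separation_flagged(self):
        rng = np.random.default_rng(3)
        Z = rng.integers(0, 2, 100).astype(float)
        X = rng.integers(0, 2, 100).astype(float)
        res = est.estimate_sem((Z, X, X.copy()))
        assert not res.valid

    @pytest.mark.parametrize("fn", [est.estimate_tsps, est.estimate_tsri])
    def test_two_stage_null(self, fn):
        cfg = SimulationConfig(alpha1=0.7, beta1=0.0, cx=0.01, cy=0.01,
                               n=100_000, seed=23)
        ds = draw_dataset(cfg, 0)
        res = fn((ds.Z, ds.X, ds.Y))
        assert res.valid
        assert abs(res.estimate) < 0.1

    def test_tsri_reports_residual_coefficient(self, small_dataset):
        ds = small_dataset
        res = est.estimate_tsri((ds.Z, ds.X, ds.Y))
        assert res.valid
        assert res.residual_coefficient is not None

    def test_tsri_without_residual_collapses_to_sem(self, small_dataset):
        ds = small_dataset
        sem = est.estimate_sem((ds.Z, ds.X, ds.Y))
        collapsed = est.fit_logistic(ds.Y, {"X": ds.X.astype(float)})
        assert collapsed.coef("X") == pytest.approx(sem.estimate, abs=1e-10)

    def test_constant_covariate_raises(self, small_dataset):
        ds = small_dataset
        with pytest.raises(est.RankDeficiencyError):
            est.estimate_tsps((ds.Z, ds.X, ds.Y), {"c0": np.zeros(ds.n)})
        with pytest.raises(est.RankDeficiencyError):
            est.wald_logistic((ds.Z, ds.X, ds.Y), {"c0": np.zeros(ds.n)})


# ---------------------------------------------------------------------------
# oracle equivalence: hand-composed statsmodels pipelines

class TestOracleEquivalence:
    TOL = 1e-6

    def test_all_six_match_hand_composition(self, small_dataset):
        ds = small_dataset
        Z, X, Y = ds.Z.astype(float), ds.X.astype(float), ds.Y.astype(float)
        px, py = X.mean(), Y.mean()

        a_log = sm_logit(X, Z)
        g_log = sm_logit(Y, Z)
        a_lin = sm_ols(X, Z)
        g_lin = sm_ols(Y, Z)

        assert est.wald_logistic((Z, X, Y)).estimate == pytest.approx(
            g_log[1] / a_log[1], abs=self.TOL)
        assert est.wald_lpm((Z, X, Y)).estimate == pytest.approx(
            (g_lin[1] / a_lin[1]) / (py * (1 - py)), abs=self.TOL)
        expected_trans = ((g_log[1] * py * (1 - py)) /
                          (a_log[1] * px * (1 - px))) / (py * (1 - py))
        assert est.wald_transformation((Z, X, Y)).estimate == pytest.approx(
            expected_trans, abs=self.TOL)

        assert est.estimate_sem((Z, X, Y)).estimate == pytest.approx(
            sm_logit(Y, X)[1], abs=self.TOL)

        first = sm.Logit(X, sm.add_constant(Z)).fit(disp=0)
        phat = first.predict()
        assert est.estimate_tsps((Z, X, Y)).estimate == pytest.approx(
            sm_logit(Y, phat)[1], abs=self.TOL)
        resid = X - phat
        tsri_params = sm_logit(Y, X, resid)
        tsri = est.estimate_tsri((Z, X, Y))
        assert tsri.estimate == pytest.approx(tsri_params[1], abs=self.TOL)
        assert tsri.residual_coefficient == pytest.approx(tsri_params[2], abs=self.TOL)

    def test_covariate_adjusted_match(self, small_dataset):
        ds = small_dataset
        Z, X, Y, U = (ds.Z.astype(float), ds.X.astype(float),
                      ds.Y.astype(float), (ds.U > 0).astype(float))
        got = est.estimate_sem((Z, X, Y), {"u": U})
        assert got.estimate == pytest.approx(sm_logit(Y, X, U)[1], abs=self.TOL)
        got_w = est.wald_logistic((Z, X, Y), {"u": U})
        assert got_w.estimate == pytest.approx(
            sm_logit(Y, Z, U)[1] / sm_logit(X, Z, U)[1], abs=self.TOL)


def test_estimate_all_matches_individual_calls(small_dataset):
    ds = small_dataset
    data = (ds.Z, ds.X, ds.Y)
    bundle = est.estimate_all(data)
    singles = {
        "logistic": est.wald_logistic(data),
        "lpm": est.wald_lpm(data),
        "transformation": est.wald_transformation(data),
    }
    for name, single in singles.items():
        assert bundle.wald[name].estimate == pytest.approx(single.estimate, abs=1e-12)
    for name, fn in [("sem", est.estimate_sem), ("tsps", est.estimate_tsps),
                     ("tsri", est.estimate_tsri)]:
        assert bundle.iv[name].estimate == pytest.approx(fn(data).estimate, abs=1e-12)
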