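import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sembiome.factor_scores import (
    MeasurementModel,
    bartlett_scores,
    compare_groups,
    extract_measurement_model,
    mann_whitney,
)
from sembiome.sem_core import SemSpec, fit_sem

from test_sem_core import simulate_two_factor

#: Published female standardized solution (loadings, residuals, latent corr).
PRINTED = {
    "lv1": {"Alistipes": 0.54, "Butyricimonas": 0.53, "Coprobacter": 0.44},
    "lv2": {"Fusicatenibacter": 0.58, "Agathobacter": 0.42, "Streptococcus": 0.20},
    "residuals": {"Alistipes": 0.70, "Butyricimonas": 0.72, "Coprobacter": 0.80,
                  "Fusicatenibacter": 0.67, "Agathobacter": 0.83,
                  "Streptococcus": 0.96},
    "c": 0.07,
}


def printed_measurement_model() -> MeasurementModel:
    names = list(PRINTED["lv1"]) + list(PRINTED["lv2"])
    return MeasurementModel(
        indicators={"lv1": list(PRINTED["lv1"]), "lv2": list(PRINTED["lv2"])},
        loadings=pd.Series({**PRINTED["lv1"], **PRINTED["lv2"]}),
        residual_variances=pd.Series(PRINTED["residuals"]),
        latent_covariance=PRINTED["c"],
        train_means=pd.Series(0.0, index=names),
        train_sds=pd.Series(1.0, index=names),
    )


@pytest.fixture(scope="module")
def fitted():
    X, y, _ = simulate_two_factor(21, 2500)
    spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
    return fit_sem(spec, X, y)


class TestExtraction:
    def test_parameters_copied_exactly(self, fitted):
        m = extract_measurement_model(fitted)
        pd.testing.assert_series_equal(m.loadings, fitted.loadings())
        pd.testing.assert_series_equal(m.residual_variances,
                                       fitted.residual_variances())
        assert m.latent_covariance == fitted.latent_correlation()
        assert fitted.spec.outcome not in m.all_indicators

    def test_extraction_idempotent(self, fitted):
        m1 = extract_measurement_model(fitted)
        m2 = extract_measurement_model(fitted)
        pd.testing.assert_series_equal(m1.loadings, m2.loadings)
        assert m1.to_text() == m2.to_text()

    def test_non_outcome_parameter_sets_match(self, fitted):
        m = extract_measurement_model(fitted)
        est = fitted.estimates
        keep = est[(est.lhs != fitted.spec.outcome) & (est.rhs != fitted.spec.outcome)]
        fitted_meas = {(r.lhs, r.op, r.rhs): r.est for r in keep.itertuples()
                       if r.op in ("=~", "~~") and not (r.lhs in ("lv1", "lv2")
                                                        and r.lhs == r.rhs)}
        for (lhs, op, rhs), val in fitted_meas.items():
            if op == "=~":
                assert m.loadings[rhs] == val
            elif lhs == rhs:
                assert m.residual_variances[lhs] == val
            else:
                assert m.latent_covariance == val

    def test_serialization_round_trip(self, fitted):
        m = extract_measurement_model(fitted)
        back = MeasurementModel.from_json(m.to_json())
        pd.testing.assert_series_equal(
            back.loadings.sort_index(), m.loadings.sort_index())
        assert back.indicators == m.indicators


class TestBartlettScores:
    def test_fixed_point_single_latent(self):
        m = MeasurementModel(
            indicators={"lv1": ["x1", "x2"], "lv2": ["z1", "z2"]},
            loadings=pd.Series({"x1": 0.6, "x2": 0.8, "z1": 0.5, "z2": 0.5}),
            residual_variances=pd.Series({"x1": 0.64, "x2": 0.36,
                                          "z1": 0.75, "z2": 0.75}),
            latent_covariance=0.0,
            train_means=pd.Series(0.0, index=["x1", "x2", "z1", "z2"]),
            train_sds=pd.Series(1.0, index=["x1", "x2", "z1", "z2"]),
        )
        clr = pd.DataFrame([[0.6, 0.8, 0.0, 0.0]], columns=["x1", "x2", "z1", "z2"],
                           index=["s1"])
        scores = bartlett_scores(m, clr)
        assert scores.table.loc["s1", "lv1"] == pytest.approx(1.0, abs=1e-12)
        assert scores.table.loc["s1", "lv2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_input_gives_zero_scores(self):
        m = printed_measurement_model()
        clr = pd.DataFrame(np.zeros((2, 6)), columns=m.all_indicators)
        scores = bartlett_scores(m, clr)
        np.testing.assert_allclose(scores.table[["lv1", "lv2"]].to_numpy(), 0.0)

    def test_matches_direct_gls_solve(self):
        # independent linear-algebra oracle on random parameters
        rng = np.random.default_rng(7)
        names = [f"v{i}" for i in range(5)]
        lam = pd.Series(rng.uniform(0.2, 0.8, 5), index=names)
        theta = pd.Series(rng.uniform(0.2, 0.9, 5), index=names)
        m = MeasurementModel(
            indicators={"lv1": names[:3], "lv2": names[3:]},
            loadings=lam, residual_variances=theta, latent_covariance=0.25,
            train_means=pd.Series(0.0, index=names),
            train_sds=pd.Series(1.0, index=names),
        )
        x = rng.standard_normal((10, 5))
        scores = bartlett_scores(m, pd.DataFrame(x, columns=names))
        L = np.zeros((5, 2))
        L[:3, 0] = lam[:3]
        L[3:, 1] = lam[3:]
        Tinv = np.diag(1 / theta.to_numpy())
        expected = np.linalg.inv(L.T @ Tinv @ L) @ L.T @ Tinv @ x.T
        np.testing.assert_allclose(scores.table[["lv1", "lv2"]].to_numpy(),
                                   expected.T, atol=1e-12)

    def test_missing_genus_named(self):
        m = printed_measurement_model()
        clr = pd.DataFrame(np.zeros((1, 5)), columns=m.all_indicators[:-1])
        with pytest.raises(ValueError, match="Streptococcus"):
            bartlett_scores(m, clr)

    def test_nonpositive_theta_rejected(self):
        m = printed_measurement_model()
        m.residual_variances["Alistipes"] = -0.1
        clr = pd.DataFrame(np.zeros((1, 6)), columns=m.all_indicators)
        with pytest.raises(ValueError, match="Alistipes"):
            bartlett_scores(m, clr)

    def test_conditional_unbiasedness(self):
        # regressing Bartlett scores on the true factor values gives slope 1
        rng = np.random.default_rng(31)
        n = 2000
        m = printed_measurement_model()
        c = m.latent_covariance
        F = rng.multivariate_normal([0, 0], [[1, c], [c, 1]], size=n)
        lam = m.loadings[m.all_indicators].to_numpy()
        fac = np.array([0, 0, 0, 1, 1, 1])
        X = F[:, fac] * lam + rng.standard_normal((n, 6)) * np.sqrt(1 - lam**2)
        scores = bartlett_scores(m, pd.DataFrame(X, columns=m.all_indicators))
        for j, lv in enumerate(["lv1", "lv2"]):
            slope = np.polyfit(F[:, j], scores.table[lv].to_numpy(), 1)[0]
            assert slope == pytest.approx(1.0, abs=0.05)

    def test_extracted_scores_track_generating_model_scores(self):
        # scores from the estimated measurement model rank samples the same
        # way as scores computed with the generating parameters
        X, y, _ = simulate_two_factor(22, 1500)
        spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        est_scores = bartlett_scores(extract_measurement_model(f), X)
        names = ["p0", "p1", "p2", "n0", "n1", "n2"]
        lam = pd.Series([0.54, 0.53, 0.44, 0.58, 0.42, 0.20], index=names)
        true_model = MeasurementModel(
            indicators={"lv1": names[:3], "lv2": names[3:]},
            loadings=lam, residual_variances=1 - lam**2, latent_covariance=0.07,
            train_means=pd.Series(0.0, index=names),
            train_sds=pd.Series(1.0, index=names),
        )
        true_scores = bartlett_scores(true_model, X)
        for lv in ("lv1", "lv2"):
            rho = stats.spearmanr(est_scores.table[lv],
                                  true_scores.table[lv]).statistic
            assert rho > 0.95


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        u, p, exact = mann_whitney(np.array([1, 2]), np.array([3, 4]))
        assert u == 0
        assert exact
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        u, p, exact = mann_whitney(np.array([5.0, 5.0]), np.array([5.0, 5.0]))
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        a, b = np.array([1.0, 4, 2]), np.array([3.0, 5])
        u1, p1, _ = mann_whitney(a, b)
        u2, p2, _ = mann_whitney(b, a)
        assert p1 == pytest.approx(p2)
        assert u2 == pytest.approx(len(a) * len(b) - u1)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=4), rng.normal(1.0, size=5)
        u, p, exact = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert exact
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=40), rng.normal(0.8, size=35)
        u, p, exact = mann_whitney(a, b)
        assert not exact
        assert 0 < p < 0.05


class TestCompareGroups:
    def test_pairwise_results(self):
        m = printed_measurement_model()
        rng = np.random.default_rng(9)
        table = pd.DataFrame({
            "lv1": rng.normal(size=30),
            "lv2": np.r_[rng.normal(size=15), rng.normal(-1.5, size=15)],
            "group": ["NC"] * 15 + ["AS"] * 15,
        }, index=[f"s{i}" for i in range(30)])
        from sembiome.factor_scores import ScoreTable

        results = compare_groups(ScoreTable(table), [("NC", "AS")], variable="lv2")
        assert results[0].p_value < 0.05
        assert 0 <= results[0].u_statistic <= 15 * 15

    def test_empty_group_rejected(self):
        from sembiome.factor_scores import ScoreTable

        table = pd.DataFrame({"lv1": [0.1], "lv2": [0.2], "group": ["NC"]},
                             index=["s1"])
        with pytest.raises(ValueError, match="empty group"):
            compare_groups(ScoreTable(table), [("NC", "AS")])
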