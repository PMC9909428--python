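import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sembiome.sem_core import (
    ModelConstructionError,
    SemSpec,
    build_model_spec,
    fit_sem,
    modify_model,
    polyserial_binary,
    rmsea,
)

FEMALE_MARKERS = {
    "Alistipes": 0.66, "Butyricimonas": -0.0, "Coprobacter": 0.5,
}


def simulate_two_factor(
    seed, n, a1=(0.54, 0.53, 0.44), a2=(0.58, 0.42, 0.20),
    b1=0.32, b2=-0.41, c=0.07, prevalence=45 / 366, extra_noise_cols=0,
):
    """Direct draw from the analysis model on the latent (CLR) scale."""
    rng = np.random.default_rng(seed)
    a1, a2 = np.asarray(a1), np.asarray(a2)
    F = rng.multivariate_normal([0, 0], [[1, c], [c, 1]], size=n)
    x1 = F[:, [0]] * a1 + rng.standard_normal((n, len(a1))) * np.sqrt(1 - a1**2)
    x2 = F[:, [1]] * a2 + rng.standard_normal((n, len(a2))) * np.sqrt(1 - a2**2)
    resv = 1 - (b1**2 + b2**2 + 2 * b1 * b2 * c)
    y_star = b1 * F[:, 0] + b2 * F[:, 1] + rng.standard_normal(n) * np.sqrt(resv)
    y = (y_star > stats.norm.ppf(1 - prevalence)).astype(int)
    cols = [f"p{i}" for i in range(len(a1))] + [f"n{i}" for i in range(len(a2))]
    X = np.hstack([x1, x2])
    if extra_noise_cols:
        X = np.hstack([X, rng.standard_normal((n, extra_noise_cols))])
        cols += [f"noise{i}" for i in range(extra_noise_cols)]
    return pd.DataFrame(X, columns=cols), y, F


class TestSpec:
    def test_female_marker_structure(self):
        markers = {"Alistipes": 0.3, "Butyricimonas": 0.28, "Coprobacter": 0.2,
                   "Fusicatenibacter": -0.5, "Agathobacter": -0.3,
                   "Streptococcus": -0.1}
        spec = build_model_spec(markers)
        assert set(spec.indicators["lv1"]) == {"Alistipes", "Butyricimonas",
                                               "Coprobacter"}
        assert set(spec.indicators["lv2"]) == {"Fusicatenibacter", "Agathobacter",
                                               "Streptococcus"}
        assert not spec.under_identified

    def test_single_indicator_flagged(self):
        spec = build_model_spec({"a": 0.5, "b": -0.2})
        assert spec.under_identified

    def test_one_sided_markers_rejected(self):
        with pytest.raises(ValueError):
            build_model_spec({"a": 0.5, "b": 0.2})

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError, match="both latents"):
            SemSpec({"lv1": ["a", "b"], "lv2": ["a", "c"]})

    def test_text_serialization(self):
        spec = SemSpec({"lv1": ["a", "b"], "lv2": ["c", "d"]})
        text = spec.to_text()
        assert "lv1 =~ a + b" in text
        assert "atopic_dermatitis ~ lv1 + lv2" in text
        assert "lv1 ~~ lv2" in text


class TestPolyserial:
    def test_recovers_latent_correlation(self):
        rng = np.random.default_rng(1)
        n = 20_000
        rho = 0.45
        x = rng.standard_normal(n)
        y_star = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        y = (y_star > stats.norm.ppf(0.8)).astype(int)
        est, var = polyserial_binary(x, y)
        assert est == pytest.approx(rho, abs=0.03)
        assert 0 < var < 1e-3


class TestFit:
    def test_noiseless_limit(self):
        rng = np.random.default_rng(0)
        n = 400
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        X = pd.DataFrame({
            "A": 0.9 * f1, "B": 0.7 * f1, "D": 0.8 * f2, "E": 0.5 * f2,
        }) + 1e-5 * rng.standard_normal((n, 4))
        y = (0.8 * f1 - 0.1 * f2 + 0.2 * rng.standard_normal(n) > 0.5).astype(int)
        f = fit_sem(SemSpec({"lv1": ["A", "B"], "lv2": ["D", "E"]}), X, y)
        np.testing.assert_allclose(np.abs(f.loadings().to_numpy()), 1.0, atol=1e-2)
        assert f.paths()["lv1"] > 0

    def test_recovery_n5000(self):
        errs = []
        for seed in range(20):
            X, y, _ = simulate_two_factor(seed, 5000, prevalence=0.12)
            if y.sum() < 10:
                continue
            spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
            f = fit_sem(spec, X, y)
            est = np.concatenate([
                f.loadings()[["p0", "p1", "p2", "n0", "n1", "n2"]].to_numpy(),
                f.paths()[["lv1", "lv2"]].to_numpy(),
            ])
            truth = np.array([0.54, 0.53, 0.44, 0.58, 0.42, 0.20, 0.32, -0.41])
            errs.append(np.abs(est - truth))
        assert np.mean(errs) < 0.05

    def test_standardization_identity(self):
        X, y, _ = simulate_two_factor(3, 800)
        spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        lam = f.loadings()
        res = f.residual_variances()
        for g in lam.index:
            assert lam[g] ** 2 + res[g] == pytest.approx(1.0, abs=1e-6)
        assert f.param("lv1", "~~", "lv1").est == 1.0
        assert f.param("lv2", "~~", "lv2").est == 1.0

    def test_outcome_flip_negates_paths_only(self):
        X, y, _ = simulate_two_factor(4, 1500)
        spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        g = fit_sem(spec, X, 1 - y)
        np.testing.assert_allclose(f.paths().to_numpy(), -g.paths().to_numpy(),
                                   atol=0.02)
        np.testing.assert_allclose(np.abs(f.loadings().to_numpy()),
                                   np.abs(g.loadings().to_numpy()), atol=0.02)

    def test_missing_variable_errors(self):
        X, y, _ = simulate_two_factor(5, 200)
        spec = SemSpec({"lv1": ["p0", "absent"], "lv2": ["n0", "n1"]})
        with pytest.raises(ValueError, match="absent"):
            fit_sem(spec, X, y)

    def test_rmsea_small_for_well_specified_model(self):
        X, y, _ = simulate_two_factor(6, 1200)
        spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        assert f.fit.rmsea < 0.08
        assert f.fit.gfi > 0.9


class TestFitIndices:
    def test_rmsea_formula(self):
        assert rmsea(100, 25, 401) == pytest.approx(np.sqrt(75 / 10_000), abs=1e-12)
        assert rmsea(100, 25, 401) == pytest.approx(0.0866, abs=5e-4)

    def test_rmsea_floor_and_df_zero(self):
        assert rmsea(20, 25, 401) == 0.0
        assert rmsea(5, 0, 100) == 0.0

    def test_near_saturated_fit(self):
        # noiseless structure: residual correlations ~ 0 -> GFI ~ 1, RMSEA 0
        rng = np.random.default_rng(2)
        n = 600
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        X = pd.DataFrame({"A": 0.8 * f1, "B": 0.6 * f1, "D": 0.7 * f2,
                          "E": 0.5 * f2}) + 0.3 * rng.standard_normal((n, 4))
        y = (0.7 * f1 + 0.3 * rng.standard_normal(n) > 0.8).astype(int)
        f = fit_sem(SemSpec({"lv1": ["A", "B"], "lv2": ["D", "E"]}), X, y)
        assert f.fit.gfi > 0.95
        assert f.fit.agfi is not None


class TestModification:
    def test_admissible_model_unchanged(self):
        X, y, _ = simulate_two_factor(8, 3000)
        spec = SemSpec({"lv1": ["p0", "p1", "p2"], "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        best, deletions = modify_model(f, X, y)
        assert deletions == []
        assert best.spec.all_indicators == spec.all_indicators

    def test_pure_noise_indicator_deleted(self):
        X, y, _ = simulate_two_factor(9, 3000, extra_noise_cols=1)
        spec = SemSpec({"lv1": ["p0", "p1", "p2", "noise0"],
                        "lv2": ["n0", "n1", "n2"]})
        f = fit_sem(spec, X, y)
        best, deletions = modify_model(f, X, y)
        deleted = {d["indicator"] for d in deletions}
        assert "noise0" in deleted
        assert "noise0" not in best.spec.all_indicators

    def test_independent_outcome_cannot_construct(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((100, 4)),
                         columns=["A", "B", "D", "E"])
        y = (rng.uniform(size=100) < 0.3).astype(int)
        f = fit_sem(SemSpec({"lv1": ["A", "B"], "lv2": ["D", "E"]}), X, y)
        with pytest.raises(ModelConstructionError, match="could not be constructed"):
            modify_model(f, X, y)

    def test_heywood_indicator_deleted_first(self):
        # correlation structure with an impossible single-factor triple:
        # r_AB * r_AC / r_BC > 1 forces loading A above 1 (negative residual)
        rng = np.random.default_rng(11)
        n = 2000
        R = np.array([
            [1.00, 0.93, 0.45, 0.05, 0.05],
            [0.93, 1.00, 0.18, 0.05, 0.05],
            [0.45, 0.18, 1.00, 0.05, 0.05],
            [0.05, 0.05, 0.05, 1.00, 0.40],
            [0.05, 0.05, 0.05, 0.40, 1.00],
        ])
        X = pd.DataFrame(
            rng.multivariate_normal(np.zeros(5), R, size=n),
            columns=["A", "B", "C", "D", "E"],
        )
        y = (0.4 * X["D"] + 0.4 * X["A"]
             + 0.6 * rng.standard_normal(n) > 0.9).astype(int)
        f = fit_sem(SemSpec({"lv1": ["A", "B", "C"], "lv2": ["D", "E"]}), X, y)
        assert f.heywood
        try:
            best, deletions = modify_model(f, X, y)
        except ModelConstructionError:
            return  # acceptable terminal outcome for an inadmissible structure
        assert any(d["phase"] == 1 for d in deletions)
        assert not best.heywood
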