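"""Doubly robust group means: hand values, equivalences, robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from deconfc.deconfound import (
    DeconfoundedGroupDifference,
    aipw_group_mean,
    bh_adjust,
    drtmle_group_mean,
    fit_outcome,
    fit_propensity,
    group_difference_z,
    naive_difference_z,
    tmle_group_mean,
)
from deconfc.synthetic import ToyParams, generate_toy_cohort, toy_truth

from conftest import outcome_library, propensity_library, toy_arrays


class TestNuisanceFits:
    def test_propensity_detects_severity_signal(self, toy_5000):
        X, a, delta, y, _ = toy_5000
        g, diag, _ = fit_propensity(X, delta, library=propensity_library(),
                                    v=5, seed=0)
        assert diag["cv_auc"] > 0.55
        assert "min_propensity" in diag and "max_propensity" in diag
        assert 0 < diag["min_propensity"] <= diag["max_propensity"] < 1

    def test_propensity_flat_when_usability_is_random(self):
        rng = np.random.default_rng(0)
        n = 5000
        X = rng.normal(size=(n, 5))
        delta = rng.binomial(1, 0.75, n)
        g, diag, _ = fit_propensity(X, delta, library=propensity_library(),
                                    v=5, seed=0)
        assert np.std(g) < 0.05
        assert abs(g.mean() - 0.75) < 0.02

    def test_propensity_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_propensity(np.zeros((20, 2)), np.ones(20))

    def test_outcome_constant_target(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        delta = rng.binomial(1, 0.8, 100)
        y = np.where(delta == 1, 2.5, np.nan)
        q, _ = fit_outcome(X, delta, y, library=outcome_library(), v=5, seed=0)
        np.testing.assert_allclose(q, 2.5, atol=1e-8)

    def test_outcome_predictions_cover_unusable_rows(self, toy_550):
        X, a, delta, y, _ = toy_550
        q, _ = fit_outcome(X, delta, y, library=outcome_library(), v=5, seed=0)
        assert q.shape == (len(delta),)
        assert np.isfinite(q[delta == 0]).all()

    def test_outcome_mse_near_irreducible_noise(self, toy_5000):
        X, a, delta, y, df = toy_5000
        q, _ = fit_outcome(X, delta, y, library=outcome_library(), v=5, seed=0)
        resid = df.Y_complete.to_numpy() - q
        assert np.mean(resid**2) < 1.1 * 0.2**2


class TestAipw:
    def test_no_missingness_reduces_to_sample_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        est = aipw_group_mean(y, np.ones(50), np.ones(50), rng.normal(size=50),
                              np.ones(50, bool))
        assert est.psi == pytest.approx(y.mean(), abs=1e-12)

    def test_two_row_hand_value(self):
        y = np.array([1.0, np.nan])
        delta = np.array([1, 0])
        g = np.array([0.5, 0.5])
        q = np.array([0.6, 0.2])
        est = aipw_group_mean(y, delta, g, q, np.ones(2, bool))
        assert est.psi == pytest.approx(0.8)

    def test_true_nuisances_recover_toy_truth(self):
        params = ToyParams(n=100_000, seed=21)
        df = generate_toy_cohort(params)
        truth = toy_truth(params)
        g = expit(2 - 0.2 * df.W_c.to_numpy())
        q = 1.4 * df.A.to_numpy() - 0.2 * df.W_c.to_numpy()
        est = aipw_group_mean(df.Y.to_numpy(), df.delta.to_numpy(), g, q,
                              df.A.to_numpy() == 1)
        assert est.psi == pytest.approx(truth.mean_asd, abs=0.01)

    def test_positivity_violation_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            aipw_group_mean(np.ones(3), np.ones(3), np.array([0.5, 0.0, 0.5]),
                            np.zeros(3), np.ones(3, bool))


class TestDrtmle:
    def test_matches_aipw_under_correct_nuisances(self):
        params = ToyParams(n=10_000, seed=22)
        df = generate_toy_cohort(params)
        g = expit(2 - 0.2 * df.W_c.to_numpy())
        q = 1.4 * df.A.to_numpy() - 0.2 * df.W_c.to_numpy()
        args = (df.Y.to_numpy(), df.delta.to_numpy(), g, q)
        for mask in (df.A.to_numpy() == 1, df.A.to_numpy() == 0):
            a_est = aipw_group_mean(*args, mask)
            d_est = drtmle_group_mean(*args, mask)
            assert d_est.psi == pytest.approx(a_est.psi, abs=0.01)
            assert d_est.se > 0

    def test_robust_to_misspecified_outcome_model(self):
        # intercept-only Q with a correct propensity: still near truth
        params = ToyParams(n=10_000, seed=23)
        df = generate_toy_cohort(params)
        truth = toy_truth(params)
        g = expit(2 - 0.2 * df.W_c.to_numpy())
        mask = df.A.to_numpy() == 1
        q_bad = np.full(len(df), df.Y[mask & (df.delta == 1)].mean())
        est = drtmle_group_mean(df.Y.to_numpy(), df.delta.to_numpy(), g, q_bad,
                                mask)
        assert est.psi == pytest.approx(truth.mean_asd, abs=0.03)


class TestEstimatorEquivalences:
    def test_all_estimators_coincide_without_missingness(self):
        rng = np.random.default_rng(3)
        n = 120
        y = rng.normal(size=n)
        a = rng.integers(0, 2, n)
        delta = np.ones(n, dtype=int)
        g = np.ones(n)
        q = rng.normal(size=n)       # arbitrary outcome model
        naive = naive_difference_z(y, delta, a)[0]
        for fn in (aipw_group_mean, tmle_group_mean, drtmle_group_mean):
            e1, e0 = fn(y, delta, g, q, a == 1, 1), fn(y, delta, g, q, a == 0, 0)
            assert e1.psi - e0.psi == pytest.approx(naive, abs=1e-8)


class TestZStatistics:
    def test_identical_estimates_give_null_z(self):
        from deconfc.deconfound import GroupMeanEstimate
        e = GroupMeanEstimate(psi=0.3, se=0.1, estimator="aipw", group=1, n=50)
        e0 = GroupMeanEstimate(psi=0.3, se=0.1, estimator="aipw", group=0, n=50)
        diff, se, z, p = group_difference_z(e, e0)
        assert (diff, z) == (0.0, 0.0) and p == 1.0

    def test_hand_arithmetic(self):
        from deconfc.deconfound import GroupMeanEstimate
        e1 = GroupMeanEstimate(psi=-0.2, se=0.05, estimator="aipw", group=1, n=50)
        e0 = GroupMeanEstimate(psi=0.0, se=0.05, estimator="aipw", group=0, n=50)
        diff, se, z, p = group_difference_z(e1, e0)
        assert z == pytest.approx(-0.2 / np.sqrt(0.005))
        assert z < 0    # negative z means ASD below TD

    def test_mismatched_estimators_rejected(self):
        from deconfc.deconfound import GroupMeanEstimate
        e1 = GroupMeanEstimate(psi=0, se=1, estimator="aipw", group=1, n=5)
        e0 = GroupMeanEstimate(psi=0, se=1, estimator="tmle", group=0, n=5)
        with pytest.raises(ValueError):
            group_difference_z(e1, e0)

    def test_naive_welch_hand_value(self):
        y = np.array([1.0, 3.0, 2.0, 4.0])
        delta = np.ones(4, int)
        a = np.array([1, 1, 0, 0])
        diff, se, z, p = naive_difference_z(y, delta, a)
        assert diff == pytest.approx(-1.0)
        assert se == pytest.approx(np.sqrt(2.0))
        assert z == pytest.approx(-1.0 / np.sqrt(2.0))

    def test_naive_is_attenuated_by_selection(self):
        # brute-force conditional mean: selection removes high-severity,
        # low-outcome ASD children, pulling the usable-case mean up
        df = generate_toy_cohort(ToyParams(n=100_000, seed=24))
        truth = toy_truth(ToyParams())
        naive = naive_difference_z(df.Y.to_numpy(), df.delta.to_numpy(),
                                   df.A.to_numpy())[0]
        assert naive > truth.mean_asd + 0.1


def _bh_oracle(p):
    """Step-up enumeration of BH adjusted values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_step_up_enumeration(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDoubleRobustnessProperty:
    def test_single_misspecification_beats_naive(self):
        # 200 toy replicates at n = 2000: either single misspecification
        # leaves under half the naive absolute mean bias
        from sklearn.dummy import DummyClassifier, DummyRegressor
        truth = toy_truth(ToyParams())
        true_diff = truth.mean_asd
        bias = {"wrong_q": [], "wrong_g": [], "naive": []}
        for r in range(200):
            X, a, delta, y, _ = toy_arrays(2000, seed=40_000 + r)
            g_ok, _, _ = fit_propensity(X, delta, library=propensity_library(),
                                        v=5, seed=r)
            q_ok, _ = fit_outcome(X, delta, y, library=outcome_library(),
                                  v=5, seed=r)
            g_bad, _, _ = fit_propensity(
                X, delta, library=[("mean", DummyClassifier(strategy="prior"))],
                v=5, seed=r)
            q_bad, _ = fit_outcome(
                X, delta, y, library=[("mean", DummyRegressor())], v=5, seed=r)
            for key, g, q in (("wrong_q", g_ok, q_bad), ("wrong_g", g_bad, q_ok)):
                e1 = aipw_group_mean(y, delta, g, q, a == 1, 1)
                e0 = aipw_group_mean(y, delta, g, q, a == 0, 0)
                bias[key].append(e1.psi - e0.psi - true_diff)
            bias["naive"].append(naive_difference_z(y, delta, a)[0] - true_diff)
        naive_bias = abs(np.mean(bias["naive"]))
        assert abs(np.mean(bias["wrong_q"])) < 0.5 * naive_bias
        assert abs(np.mean(bias["wrong_g"])) < 0.5 * naive_bias


class TestPipeline:
    def _toy_frame(self, n, seed):
        df = generate_toy_cohort(ToyParams(n=n, seed=seed))
        X = df.drop(columns=["Y", "Y_complete"])
        return X, df.Y.to_numpy()

    def test_single_seed_pipeline_matches_manual_run(self):
        X, y = self._toy_frame(800, seed=30)
        model = DeconfoundedGroupDifference(
            estimator="aipw", propensity_library=propensity_library(),
            outcome_library=outcome_library(), v=5, seed=3, n_seeds=1)
        model.fit(X, y)
        res = model.results_
        assert len(res) == 1
        assert res.loc[0, "q"] == pytest.approx(res.loc[0, "p"])
        assert set(res.columns) >= {"psi_asd", "psi_td", "z", "p", "q",
                                    "sign", "naive_z"}
        # single-seed averaged z is the per-seed z
        assert res.loc[0, "z"] == pytest.approx(model.z_per_seed_[0, 0])
        assert model.diagnostics_["n_seeds_completed"] == 1

    def test_fdr_levels_reported(self):
        X, y = self._toy_frame(600, seed=31)
        model = DeconfoundedGroupDifference(
            estimator="aipw", propensity_library=propensity_library(),
            outcome_library=outcome_library(), v=5, seed=0, n_seeds=1,
            fdr_levels=(0.2, 0.05))
        model.fit(X, y)
        assert {"significant_fdr_0.2", "significant_fdr_0.05"} <= set(
            model.results_.columns)

    def test_sklearn_param_protocol(self):
        model = DeconfoundedGroupDifference(estimator="aipw", v=7)
        assert model.get_params()["v"] == 7
        model.set_params(v=4, estimator="tmle")
        assert model.get_params()["estimator"] == "tmle"

    def test_missing_required_columns_rejected(self):
        model = DeconfoundedGroupDifference()
        with pytest.raises(ValueError, match="delta"):
            model.fit(pd.DataFrame({"A": [0, 1]}), np.zeros(2))
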