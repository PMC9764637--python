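"""Censored SVR: QP-oracle equivalence, censoring economics, risk scaling,
threshold search, and PSO behaviour."""

import json

import numpy as np
import pandas as pd
import pytest

from morphrisk._util import round_half_up
from morphrisk.metrics import horizon_confusion
from morphrisk.pso import pso_minimize
from morphrisk.svrc import (
    SVRcHyperparams,
    SVRcModel,
    cv_concordance,
    fit_svrc,
    predict_risk,
    pso_optimize,
    raw_to_score,
    select_threshold,
    solve_svrc,
)

from svr_oracle import solve_qp_primal


def _random_instance(rng, n=20, d=3):
    X = rng.standard_normal((n, d))
    y = X @ rng.standard_normal(d) + 0.3 * rng.standard_normal(n) + rng.uniform(-2, 2)
    return X, y


class TestSolverOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_asymmetric_censored_instance_matches_generic_qp(self, seed):
        # per-patient asymmetric penalties/margins, the general configuration
        rng = np.random.default_rng(100 + seed)
        X, y = _random_instance(rng)
        n = len(y)
        delta = rng.random(n) > 0.4
        hp = SVRcHyperparams(
            C_event_over=rng.uniform(0.5, 5),
            C_event_under=rng.uniform(0.5, 5),
            C_cens_over=rng.uniform(0.01, 0.5),
            C_cens_under=rng.uniform(0.5, 5),
            eps_event_over=rng.uniform(0, 0.4),
            eps_event_under=rng.uniform(0, 0.4),
            eps_cens_over=rng.uniform(0, 1.0),
            eps_cens_under=rng.uniform(0, 0.4),
        )
        Co, Cu, eo, eu = hp.per_patient(delta)
        w1, b1, _ = solve_svrc(X, y, Co, Cu, eo, eu, mode="exact")
        w2, b2 = solve_qp_primal(X, y, Co, Cu, eo, eu)
        assert np.max(np.abs((X @ w1 + b1) - (X @ w2 + b2))) < 1e-6

    def test_interpolation_limit_recovers_exact_line(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, (25, 1))
        y = 3.0 * X[:, 0] + 1.5
        m = fit_svrc(
            X, y, np.ones(25, dtype=int),
            SVRcHyperparams(
                C_event_over=1e6, C_event_under=1e6,
                eps_event_over=0.0, eps_event_under=0.0,
            ),
        )
        assert np.max(np.abs(m.predict_raw(X) - y)) < 1e-6

    def test_unpenalized_censored_overprediction_is_ignorable(self):
        # a censored follow-up far below the fitted line costs nothing when
        # C_cens_over ~ 0, so removing that patient leaves the fit unchanged
        rng = np.random.default_rng(2)
        X = rng.uniform(-2, 2, (20, 1))
        y = 2.0 * X[:, 0] + 10 + 0.1 * rng.standard_normal(20)
        X_all = np.vstack([X, [[0.0]]])
        y_all = np.append(y, 2.0)  # far below the line at x=0
        delta = np.append(np.ones(20, dtype=int), 0)
        hp = SVRcHyperparams(C_cens_over=1e-9, eps_cens_over=0.0)
        m_with = fit_svrc(X_all, y_all, delta, hp)
        m_without = fit_svrc(X, y, np.ones(20, dtype=int), hp)
        grid = np.linspace(-2, 2, 50)[:, None]
        # compare on the unstandardized scale: refit standardization differs
        diff = np.max(np.abs(
            (m_with._matrix(grid) @ m_with.weights + m_with.bias)
            - (m_without._matrix(grid) @ m_without.weights + m_without.bias)
        ))
        assert diff < 1e-5

    def test_stronger_censored_overprediction_penalty_pushes_fit_down(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (30, 1))
        y = 2.0 * X[:, 0] + 10
        delta = np.ones(30, dtype=int)
        delta[:10] = 0
        y = y.copy()
        y[:10] -= 5.0  # censored points sit below the trend
        preds = []
        for c in (0.01, 0.1, 1.0, 10.0):
            hp = SVRcHyperparams(C_cens_over=c)
            m = fit_svrc(X, y, delta, hp)
            preds.append(m.predict_raw(X)[:10])
        for lo, hi in zip(preds, preds[1:]):
            assert (hi <= lo + 1e-6).all()

    def test_log_time_switch_preserves_risk_ordering(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 2))
        y = 30 * np.exp(1.0 + 0.8 * X[:, 0] + 0.1 * rng.standard_normal(60))
        delta = np.ones(60, dtype=int)
        m_lin = fit_svrc(X, y, delta)
        # margins live on the target scale, so shrink them for log months
        hp_log = SVRcHyperparams(
            eps_event_over=0.05, eps_event_under=0.05,
            eps_cens_over=0.1, eps_cens_under=0.05,
        )
        m_log = fit_svrc(X, y, delta, hp_log, log_time=True)
        r_lin = raw_to_score(m_lin, m_lin.predict_raw(X))
        r_log = raw_to_score(m_log, m_log.predict_raw(X))
        from scipy.stats import spearmanr
        assert spearmanr(r_lin, r_log).statistic > 0.9

    def test_missing_values_and_no_events_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError):
            fit_svrc(X, [1.0, 2.0, np.nan, 3.0], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit_svrc(X, [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])


class TestRiskScaling:
    def _model(self):
        return SVRcModel(
            feature_names=["f"],
            weights=np.array([1.0]),
            bias=0.0,
            feature_mean=np.array([0.0]),
            feature_sd=np.array([1.0]),
            train_min=-2.0,
            train_max=2.0,
            hyperparams=SVRcHyperparams(),
            threshold_reported=58,
        )

    def test_range_endpoints_map_to_0_and_100(self):
        m = self._model()
        assert raw_to_score(m, np.array([2.0]))[0] == 0.0
        assert raw_to_score(m, np.array([-2.0]))[0] == 100.0

    def test_out_of_range_predictions_clip(self):
        m = self._model()
        assert raw_to_score(m, np.array([5.0]))[0] == 0.0
        assert raw_to_score(m, np.array([-9.0]))[0] == 100.0

    def test_score_monotone_decreasing_in_raw_prediction(self):
        m = self._model()
        raw = np.linspace(-3, 3, 50)
        s = raw_to_score(m, raw)
        assert (np.diff(s) <= 1e-12).all()

    def test_strata_respect_reported_threshold_exactly(self):
        m = self._model()
        X = pd.DataFrame({"f": np.linspace(-3, 3, 101)})
        rs = predict_risk(m, X)
        assert ((rs.score >= 58) == (rs.stratum == "high")).all()

    def test_feature_name_mismatch_is_an_error(self):
        m = self._model()
        with pytest.raises(ValueError, match="mismatch"):
            m.predict_raw(pd.DataFrame({"g": [1.0]}))

    def test_json_round_trip(self):
        m = self._model()
        m2 = SVRcModel.from_json(m.to_json())
        assert m2.feature_names == m.feature_names
        assert np.allclose(m2.weights, m.weights)
        assert m2.threshold_reported == 58
        assert json.loads(m.to_json())["hyperparams"]["C_cens_over"] == 0.1


class TestThresholdSelection:
    def test_separated_scores_pick_lowest_winning_cut(self):
        scores = np.array([10.0, 20.0, 30.0, 70.0, 80.0, 90.0])
        time = np.array([100, 100, 100, 10, 20, 30.0])
        event = np.array([0, 0, 0, 1, 1, 1])
        thr, rep = select_threshold(scores, time, event, 72.0)
        assert thr == 70.0  # any cut in (30, 70] is perfect; candidates are
        # observed scores and ties break low
        assert rep == 70

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(0, 100, 10), 1)
        time = rng.exponential(80, 10)
        event = (rng.random(10) > 0.3).astype(int)
        if not ((event == 1) & (time <= 72)).any() or not (time >= 72).any():
            pytest.skip("degenerate draw")
        thr, _ = select_threshold(scores, time, event, 72.0)
        best_j, best_t = -np.inf, None
        for t in np.unique(scores):
            c = horizon_confusion(scores, t, time, event, 72.0)
            j = c.sensitivity + c.specificity
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        assert thr == best_t

    def test_reported_threshold_uses_half_up_rounding(self):
        assert round_half_up(57.77) == 58
        assert round_half_up(57.5) == 58
        assert round_half_up(57.49) == 57

    def test_no_evaluable_patients_is_an_error(self):
        with pytest.raises(ValueError):
            select_threshold([50.0, 60.0], [10.0, 20.0], [1, 1], 72.0)


class TestPSO:
    def test_sphere_benchmark_converges(self):
        center = np.array([1.0, -2.0, 0.5, 3.0])
        res = pso_minimize(
            lambda x: float(((x - center) ** 2).sum()),
            bounds=np.array([[-5.0, 5.0]] * 4),
            n_particles=20,
            n_iter=500,
            seed=0,
        )
        assert np.max(np.abs(res.x - center)) < 1e-3

    def test_same_seed_gives_identical_hyperparameters(self):
        rng = np.random.default_rng(4)
        X, y = _random_instance(rng, n=60, d=3)
        delta = (rng.random(60) > 0.3).astype(int)
        hp1 = pso_optimize(X, np.abs(y) + 1, delta, seed=3, n_particles=4, n_iter=3)
        hp2 = pso_optimize(X, np.abs(y) + 1, delta, seed=3, n_particles=4, n_iter=3)
        assert hp1 == hp2

    def test_zero_iterations_returns_seeded_initial_position(self):
        bounds = np.array([[-1.0, 1.0]] * 2)
        res = pso_minimize(lambda x: float(x @ x), bounds, n_particles=1, n_iter=0, seed=9)
        rng = np.random.default_rng(9)
        expected = bounds[:, 0] + rng.random((1, 2)) * (bounds[:, 1] - bounds[:, 0])
        assert np.allclose(res.x, expected[0])

    def test_tuner_respects_censoring_penalty_ordering(self):
        rng = np.random.default_rng(5)
        X, y = _random_instance(rng, n=80, d=2)
        delta = (rng.random(80) > 0.3).astype(int)
        hp = pso_optimize(X, np.abs(y) + 1, delta, seed=1, n_particles=5, n_iter=4)
        assert hp.C_cens_over <= hp.C_event_over


class TestCrossValidation:
    def test_cv_concordance_detects_signal_and_null(self):
        rng = np.random.default_rng(6)
        n = 300
        X = rng.standard_normal((n, 3))
        eta = 1.2 * X[:, 0]
        t = 50 * rng.exponential(size=n) / np.exp(eta)
        c = rng.uniform(0, 120, n)
        y = np.minimum(t, c)
        delta = (t <= c).astype(int)
        signal = cv_concordance(X, y, delta, SVRcHyperparams(), 5, 0)
        assert signal > 0.65
        X_null = rng.standard_normal((n, 3))
        null = cv_concordance(X_null, y, delta, SVRcHyperparams(), 5, 0)
        assert 0.4 < null < 0.6
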