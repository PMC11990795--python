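import warnings

import numpy as np
import pytest

from nirboost import adaboost_fit, ensemble_predict, pls_fit
from nirboost.ensemble import EnsembleModel, graded_loss
from nirboost.errors import FitError


@pytest.fixture
def fitted_member(rng):
    X = rng.normal(size=(30, 5))
    y = X @ rng.normal(size=5) + rng.normal(size=30) * 0.1
    return pls_fit(X, y, n_lv=3), X, y


class TestGradedLoss:
    def test_piecewise_values(self):
        d = np.array([0.0, 0.5, 1.0, 1.25, 1.5, 2.0])
        loss = graded_loss(d, 1.0, 1.5)
        assert np.allclose(loss, [0.0, 0.25, 0.5, 0.75, 1.0, 1.0])

    def test_bounded_and_monotone(self, rng):
        d = np.sort(np.abs(rng.normal(size=100) * 3))
        loss = graded_loss(d, 1.0, 1.5)
        assert np.all((loss >= 0) & (loss <= 1))
        assert np.all(np.diff(loss) >= 0)

    def test_bad_thresholds(self):
        with pytest.raises(FitError):
            graded_loss(np.array([1.0]), 1.5, 1.0)


class TestAdaboostFit:
    def test_identical_members_equal_weights(self, fitted_member):
        model, X, y = fitted_member
        pred = model.predict(X)
        ens = adaboost_fit(
            [model, model, model], X, y, member_predictions=[pred, pred, pred]
        )
        assert np.allclose(ens.weights, 1.0 / 3.0, atol=1e-15)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_member_closed_form(self, fitted_member):
        model, X, y = fitted_member
        n = y.size
        # deviations chosen so the graded losses are exactly 0.1 and 0.4
        # under uniform sample weights: eps1 = 0.1, eps2 = 0.4
        pred1 = y + 0.2  # d = 0.2 <= t1 -> loss = 0.1
        pred2 = y + 0.8  # d = 0.8 <= t1 -> loss = 0.4
        ens = adaboost_fit(
            [model, model], X, y, member_predictions=[pred1, pred2]
        )
        # alpha_m = ln((1 - eps)/eps): ln(9) and ln(1.5)
        expected_ratio = np.log(9.0) / np.log(1.5)
        assert ens.weights[0] / ens.weights[1] == pytest.approx(
            expected_ratio, rel=1e-12
        )
        assert np.allclose(ens.training_errors, [0.1, 0.4])

    def test_single_member_degenerate(self, fitted_member):
        model, X, y = fitted_member
        ens = adaboost_fit([model], X, y, member_predictions=[model.predict(X)])
        assert ens.weights.tolist() == [1.0]
        assert np.array_equal(ens.predict(X), model.predict(X))

    def test_high_error_member_downweighted(self, fitted_member):
        model, X, y = fitted_member
        good = y + 0.2
        bad = y + 5.0  # loss 1 everywhere -> eps ~ 1
        with pytest.warns(UserWarning, match=">= 0.5"):
            ens = adaboost_fit(
                [model, model], X, y, member_predictions=[good, bad]
            )
        assert ens.weights[1] == 0.0
        assert ens.weights[0] == 1.0

    def test_all_bad_falls_back_uniform(self, fitted_member):
        model, X, y = fitted_member
        bad = y + 5.0
        with pytest.warns(UserWarning):
            ens = adaboost_fit(
                [model, model], X, y, member_predictions=[bad, bad]
            )
        assert np.allclose(ens.weights, 0.5)

    def test_sequential_mode_matches_manual_update(self, fitted_member):
        # oracle: re-derive the sweep by hand with w <- w * beta^(1 - loss)
        model, X, y = fitted_member
        rng = np.random.default_rng(5)
        preds = [y + rng.normal(size=y.size) * s for s in (0.3, 0.5, 0.7)]
        ens = adaboost_fit(
            [model] * 3, X, y, member_predictions=preds,
            update_sample_weights=True,
        )
        n = y.size
        w = np.full(n, 1.0 / n)
        alphas = []
        for pred in preds:
            loss = graded_loss(pred - y, 1.0, 1.5)
            eps = float(np.clip(w @ loss, 1 / (2 * n), 1 - 1 / (2 * n)))
            beta = eps / (1 - eps)
            alphas.append(np.log(1 / beta))
            w = w * beta ** (1 - loss)
            assert np.all(w >= 0)
            w = w / w.sum()
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
        expected = np.array(alphas) / np.sum(alphas)
        assert np.allclose(ens.weights, expected, atol=1e-12)

    def test_cv_predictions_computed_when_missing(self, fitted_member):
        model, X, y = fitted_member
        ens = adaboost_fit([model, model], X, y, k=5, seed=0)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ens.weights >= 0)


class TestEnsemblePredict:
    def test_identical_members_reproduce_member(self, fitted_member):
        model, X, _ = fitted_member
        ens = EnsembleModel(members=[model, model],
                            weights=np.array([0.5, 0.5]))
        assert np.allclose(ens.predict(X), model.predict(X))

    def test_constant_members_predict_constant(self, rng):
        # members with zero slope always output their intercept
        from nirboost.plsr import PLSModel

        member = PLSModel(
            n_lv=1, x_mean=np.zeros(4), x_sd=np.ones(4), y_mean=22.0,
            coefficients=np.zeros(4), intercept=22.0,
            variable_indices=np.arange(4),
        )
        ens = EnsembleModel(members=[member, member, member],
                            weights=np.full(3, 1 / 3))
        out = ens.predict(rng.normal(size=(6, 4)))
        assert np.allclose(out, 22.0)

    def test_degenerate_weights_select_member(self, fitted_member, rng):
        model, X, y = fitted_member
        other = pls_fit(X, y + rng.normal(size=30), n_lv=2)
        ens = EnsembleModel(members=[model, other, other],
                            weights=np.array([1.0, 0.0, 0.0]))
        assert np.array_equal(ens.predict(X), model.predict(X))

    def test_convexity(self, rng):
        X = rng.normal(size=(40, 8))
        members = [
            pls_fit(X, X @ rng.normal(size=8) + rng.normal(size=40), n_lv=2)
            for _ in range(3)
        ]
        w = rng.dirichlet(np.ones(3))
        ens = EnsembleModel(members=members, weights=w)
        X_new = rng.normal(size=(15, 8))
        stacked = np.stack([m.predict(X_new) for m in members])
        combined = ens.predict(X_new)
        assert np.all(combined <= stacked.max(axis=0) + 1e-12)
        assert np.all(combined >= stacked.min(axis=0) - 1e-12)

    def test_missing_columns_named(self, fitted_member):
        model, X, _ = fitted_member
        ens = EnsembleModel(members=[model], weights=np.array([1.0]))
        with pytest.raises(FitError, match="columns"):
            ens.predict(X[:, :3])
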