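"""Burg AR and MVAR estimation against generating-process oracles."""

import numpy as np
import pytest

from dtfnet import MVARModel, fit_ar_burg, fit_mvar, select_order_aic, simulate_mvar
from dtfnet.exceptions import EstimationError, OrderSelectionError
from dtfnet.mvar import LEAST_SQUARES, MULTICHANNEL_BURG


def _ar_model(coeffs, fs=500.0, noise_var=1.0):
    """Univariate AR as a 1-channel MVAR (shared simulation path)."""
    p = len(coeffs)
    return MVARModel(
        order=p,
        coeff_mats=np.asarray(coeffs, dtype=float).reshape(p, 1, 1),
        noise_cov=np.asarray([[noise_var]]),
        fs=fs,
    )


STABLE_3CH = MVARModel(
    order=2,
    coeff_mats=np.asarray(
        [
            [[0.5, 0.1, 0.0], [0.3, 0.4, 0.0], [0.0, 0.2, 0.5]],
            [[-0.2, 0.0, 0.0], [0.0, -0.1, 0.1], [0.1, 0.0, -0.2]],
        ]
    ),
    noise_cov=np.eye(3),
    fs=500.0,
)


class TestBurg:
    def test_recovers_simulated_ar2(self):
        truth = [0.6, -0.3]
        x = simulate_mvar(_ar_model(truth), 4000, seed=7)[0]
        fit = fit_ar_burg(x, order=2)
        assert np.max(np.abs(fit.coeffs - truth)) < 0.05
        assert abs(fit.noise_var - 1.0) < 0.1

    def test_white_noise_has_small_coefficient(self, rng):
        x = rng.standard_normal(4000) * 2.0
        fit = fit_ar_burg(x, order=1)
        assert abs(fit.coeffs[0]) < 0.1
        assert abs(fit.noise_var - 4.0) < 0.4

    def test_noise_free_decay_matches_closed_form(self):
        # On the deterministic recursion x(n) = a x(n-1) the order-1 Burg
        # reflection coefficient has the closed form 2a/(1+a^2): the
        # backward prediction error of the decaying path pulls the combined
        # forward+backward minimiser away from a itself. (With stationary
        # noise-driven data Burg is consistent for a; see the AR(2) test.)
        a = 0.9
        x = a ** np.arange(200)
        # statsmodels demeans internally; hand the demeaned series its own
        # closed form by removing the mean from the oracle computation too
        xc = x - x.mean()
        expected = 2 * np.sum(xc[1:] * xc[:-1]) / (np.sum(xc[1:] ** 2) + np.sum(xc[:-1] ** 2))
        fit = fit_ar_burg(x, order=1)
        assert abs(fit.coeffs[0] - expected) < 1e-9
        assert abs(fit.coeffs[0] - 2 * a / (1 + a * a)) < 5e-3

    def test_too_short_and_constant_series_rejected(self):
        with pytest.raises(EstimationError):
            fit_ar_burg(np.arange(8.0), order=4)
        with pytest.raises(EstimationError, match="constant"):
            fit_ar_burg(np.ones(100), order=2)


class TestMVARFit:
    @pytest.mark.parametrize("method", [LEAST_SQUARES, MULTICHANNEL_BURG])
    def test_recovers_known_coefficients(self, method):
        x = simulate_mvar(STABLE_3CH, 5000, seed=11)
        fit = fit_mvar(x, order=2, fs=500.0, method=method)
        assert np.max(np.abs(fit.coeff_mats - STABLE_3CH.coeff_mats)) < 0.05
        assert np.max(np.abs(fit.noise_cov - np.eye(3))) < 0.1

    def test_independent_channels_give_zero_coupling(self, rng):
        x = rng.standard_normal((2, 5000))
        fit = fit_mvar(x, order=1)
        assert np.max(np.abs(fit.coeff_mats)) < 0.05

    def test_fit_simulate_refit_self_consistency(self):
        x = simulate_mvar(STABLE_3CH, 5000, seed=3)
        first = fit_mvar(x, order=2, fs=500.0)
        x2 = simulate_mvar(first, 5000, seed=4)
        second = fit_mvar(x2, order=2, fs=500.0)
        assert np.max(np.abs(first.coeff_mats - second.coeff_mats)) < 0.1

    def test_residuals_orthogonal_to_regressors(self):
        x = simulate_mvar(STABLE_3CH, 2000, seed=5)
        fit = fit_mvar(x, order=2)
        xc = x - x.mean(axis=1, keepdims=True)
        T = xc.shape[1]
        Z = np.concatenate([xc[:, 2 - k : T - k] for k in (1, 2)], axis=0).T
        resid = xc[:, 2:].T - Z @ np.concatenate(list(fit.coeff_mats), axis=1).T
        rel = np.abs(Z.T @ resid).max() / (np.abs(Z).max() * np.abs(resid).max() * T)
        assert rel < 1e-6

    def test_single_channel_matches_univariate_least_squares(self):
        x = simulate_mvar(_ar_model([0.6, -0.3]), 1000, seed=9)
        fit = fit_mvar(x, order=2)
        xc = (x - x.mean())[0]
        Z = np.column_stack([xc[1:-1], xc[:-2]])
        beta = np.linalg.lstsq(Z, xc[2:], rcond=None)[0]
        assert np.max(np.abs(fit.coeff_mats[:, 0, 0] - beta)) < 1e-10

    def test_error_shrinks_with_sample_size(self):
        errs = {n: [] for n in (1000, 10000)}
        for seed in range(20):
            for n in errs:
                x = simulate_mvar(STABLE_3CH, n, seed=100 + seed)
                fit = fit_mvar(x, order=2)
                errs[n].append(np.max(np.abs(fit.coeff_mats - STABLE_3CH.coeff_mats)))
        assert np.median(errs[10000]) < np.median(errs[1000])

    def test_agrees_with_statsmodels_var(self):
        # independent implementation of the same least-squares problem
        from statsmodels.tsa.api import VAR

        x = simulate_mvar(STABLE_3CH, 4000, seed=21)
        ours = fit_mvar(x, order=2)
        theirs = VAR((x - x.mean(axis=1, keepdims=True)).T).fit(maxlags=2, trend="n")
        assert np.max(np.abs(ours.coeff_mats - theirs.coefs)) < 5e-3

    def test_too_short_trial_rejected(self, rng):
        with pytest.raises(EstimationError, match="too short"):
            fit_mvar(rng.standard_normal((3, 8)), order=3)

    def test_rank_deficiency_reported(self):
        x = np.zeros((2, 100))
        x[0] = np.sin(np.arange(100))
        x[1] = x[0]  # duplicated channel -> collinear regressors
        with pytest.raises(EstimationError):
            fit_mvar(x, order=4)


class TestOrderSelection:
    def _mvar3(self):
        mats = np.zeros((3, 3, 3))
        mats[0] = [[0.4, 0.2, 0.0], [0.0, 0.3, 0.2], [0.1, 0.0, 0.4]]
        mats[1] = [[-0.2, 0.0, 0.1], [0.0, -0.2, 0.0], [0.0, 0.1, -0.2]]
        mats[2] = [[0.15, 0.0, 0.0], [0.1, 0.15, 0.0], [0.0, 0.0, 0.15]]
        return MVARModel(order=3, coeff_mats=mats, noise_cov=np.eye(3), fs=500.0)

    def test_selects_generating_order(self):
        model = self._mvar3()
        hits = 0
        for seed in range(50):
            x = simulate_mvar(model, 5000, seed=seed)
            if select_order_aic(x, p_max=10).order == 3:
                hits += 1
        assert hits >= 40  # >= 80% of replicates

    def test_white_noise_prefers_order_one(self, rng):
        picks = [select_order_aic(rng.standard_normal((3, 2000)), p_max=5).order for _ in range(20)]
        assert np.bincount(picks).argmax() == 1

    def test_single_candidate(self):
        x = simulate_mvar(STABLE_3CH, 1000, seed=2)
        assert select_order_aic(x, p_max=1).order == 1

    def test_curve_finite_and_determinant_monotone(self):
        x = simulate_mvar(STABLE_3CH, 3000, seed=6)
        sel = select_order_aic(x, p_max=8)
        assert np.isfinite(sel.aic).all()
        # recover log-dets from the AIC definition and check monotonicity
        n_eff = x.shape[1] - 8
        logdets = (sel.aic - 2.0 * sel.orders * 9) / n_eff
        assert np.all(np.diff(logdets) <= 1e-10)

    def test_impossible_search_rejected(self, rng):
        with pytest.raises(OrderSelectionError):
            select_order_aic(rng.standard_normal((3, 30)), p_max=20)
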