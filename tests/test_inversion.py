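"""Monte-Carlo activity inversion, correlation scoring and ROC analysis."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_curve

import h2axdose as hx
import h2axdose.inversion as inv
from h2axdose.presets import BLOOD_BESTFIT


def grid_argmin(psi, time, fluorescence, a_lo, a_hi, step=1e-3):
    """Dense-grid brute-force minimiser of the squared calibration residual."""
    grid = np.arange(a_lo, a_hi + step, step)
    F = hx.predict_fluorescence(psi, activity=grid, time=time)
    return grid[np.argmin((F - fluorescence) ** 2)]


class TestEstimateActivity:
    def test_exact_roundtrip_high_branch(self):
        F = hx.predict_fluorescence(BLOOD_BESTFIT, activity=5.74, time=2.0)
        a, flag = inv.estimate_activity(BLOOD_BESTFIT, 2.0, F, branch="high")
        assert flag == "ok"
        assert a == pytest.approx(5.74, abs=1e-4)

    def test_background_fluorescence_flagged_out_of_range(self):
        a, flag = inv.estimate_activity(BLOOD_BESTFIT, 2.0, BLOOD_BESTFIT.b)
        assert flag == "out_of_range"
        assert a == pytest.approx(20.0)  # far boundary of the search range

    def test_saturating_fluorescence_returns_peak_activity(self):
        a_peak = hx.activity_of_max_response(BLOOD_BESTFIT)
        ceiling = hx.predict_fluorescence(BLOOD_BESTFIT, activity=a_peak, time=2.0)
        a, flag = inv.estimate_activity(BLOOD_BESTFIT, 2.0, ceiling + 10.0)
        assert flag == "saturated"
        assert a == pytest.approx(a_peak, rel=1e-9)

    def test_low_branch_conjugate_root_matches_grid_oracle(self):
        F = hx.predict_fluorescence(BLOOD_BESTFIT, activity=5.74, time=2.0)
        a_low, flag = inv.estimate_activity(BLOOD_BESTFIT, 2.0, F, branch="low")
        assert flag == "ok"
        a_peak = hx.activity_of_max_response(BLOOD_BESTFIT)
        assert a_low < a_peak < 5.74
        oracle = grid_argmin(BLOOD_BESTFIT, 2.0, F, 0.001, a_peak)
        assert a_low == pytest.approx(oracle, abs=2e-3)
        # both roots reproduce the measured fluorescence equally well
        f_low = hx.predict_fluorescence(BLOOD_BESTFIT, activity=a_low, time=2.0)
        assert f_low == pytest.approx(F, rel=1e-9)

    def test_global_branch_prefers_smaller_residual(self):
        F = hx.predict_fluorescence(BLOOD_BESTFIT, activity=5.74, time=2.0)
        a, _ = inv.estimate_activity(BLOOD_BESTFIT, 2.0, F, branch="global")
        # exact tie between branches resolves to the falling limb
        assert a == pytest.approx(5.74, abs=1e-4)

    def test_monotone_on_falling_limb(self):
        # larger measured fluorescence maps to smaller estimated activity
        # stay below the response ceiling at t = 2 d (~1339 AU)
        Fs = np.linspace(1100.0, 1330.0, 30)
        a = np.array(
            [inv.estimate_activity(BLOOD_BESTFIT, 2.0, F, branch="high")[0] for F in Fs]
        )
        assert np.all(np.diff(a) < 0)

    def test_invalid_branch_rejected(self):
        with pytest.raises(ValueError):
            inv.estimate_activity(BLOOD_BESTFIT, 2.0, 1200.0, branch="middle")


class TestEnsembleSampling:
    def test_all_draws_satisfy_deviance_rule(self, noisy_fit, small_ensemble):
        thr = stats.chi2.ppf(0.95, df=4)
        dev = 2.0 * (
            noisy_fit.model.nloglike_free(
                small_ensemble.k,
                small_ensemble.alpha,
                small_ensemble.r,
                small_ensemble.p,
            )
            - noisy_fit.nll
        )
        assert np.all(dev <= thr + 1e-9)

    def test_best_fit_is_first_accepted_draw(self, noisy_fit, small_ensemble):
        psi0 = small_ensemble.draw(0)
        for name in ("k", "alpha", "r", "p"):
            assert getattr(psi0, name) == pytest.approx(
                getattr(noisy_fit.params, name), rel=1e-9
            )

    def test_reproducible_under_seed(self, noisy_fit):
        e1 = noisy_fit.sample_confidence_region(n_min=200, seed=5)
        e2 = noisy_fit.sample_confidence_region(n_min=200, seed=5)
        assert np.array_equal(e1.k, e2.k) and np.array_equal(e1.p, e2.p)

    def test_tiny_proposal_scale_accepts_everything(self, noisy_fit):
        ens = noisy_fit.sample_confidence_region(
            n_min=100, seed=1, proposal_scale=np.full(4, 1e-6)
        )
        assert ens.acceptance_rate > 0.99


class TestSummarizeEstimates:
    def test_single_draw_collapses_summary(self, noisy_fit):
        ens = noisy_fit.sample_confidence_region(
            n_min=1, seed=2, proposal_scale=np.full(4, 1e-6)
        )
        F = hx.predict_fluorescence(noisy_fit.params, activity=7.65, time=3.0)
        (est,) = inv.summarize_estimates(ens, [(3.0, F, 7.65)])
        assert est.median_activity == est.min_activity == est.max_activity

    def test_noise_free_points_recovered(self, noisy_fit, small_ensemble):
        points = [
            (t, hx.predict_fluorescence(noisy_fit.params, activity=a, time=t), a)
            for a in (7.65, 9.28)
            for t in (2.0, 5.0)
        ]
        for est in inv.summarize_estimates(small_ensemble, points):
            assert est.min_activity <= est.median_activity <= est.max_activity

    def test_wider_region_never_narrows_range(self, noisy_fit):
        e95 = noisy_fit.sample_confidence_region(n_min=400, seed=3, level=0.95)
        e99 = noisy_fit.sample_confidence_region(
            n_min=400, seed=3, level=0.99, proposal_scale=e95.proposal_scale
        )
        F = hx.predict_fluorescence(noisy_fit.params, activity=9.28, time=3.0)
        (est95,) = inv.summarize_estimates(e95, [(3.0, F)])
        (est99,) = inv.summarize_estimates(e99, [(3.0, F)])
        # the 99% region is a superset, so the spread cannot shrink
        assert est99.max_activity - est99.min_activity >= (
            est95.max_activity - est95.min_activity
        ) * (1 - 1e-9)

    def test_all_draws_flagged_marks_point_undefined(self, small_ensemble):
        (est,) = inv.summarize_estimates(
            small_ensemble, [(2.0, small_ensemble.background - 50.0)]
        )
        assert est.undefined and math.isnan(est.median_activity)


class TestCorrelationReport:
    def _estimates(self, pairs, day=2.0):
        return [
            inv.ActivityEstimate(
                time=day, measured_fluorescence=0.0, median_activity=y,
                min_activity=y, max_activity=y, true_activity=x,
            )
            for x, y in pairs
        ]

    def test_perfectly_ordered_gives_rho_one(self):
        est = self._estimates([(1, 1), (2, 2), (3, 3), (4, 4)])
        rep = inv.correlation_report(est, [(2, 3)])
        assert rep.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_anti_ordered_gives_rho_minus_one(self):
        est = self._estimates([(1, 4), (2, 3), (3, 2), (4, 1)])
        rep = inv.correlation_report(est, [(2, 3)])
        assert rep.loc[0, "spearman_rho"] == pytest.approx(-1.0)
        # exact permutation p for |rho| = 1 with n = 4: 2 of 24 orderings
        assert rep.loc[0, "spearman_p"] == pytest.approx(2 / 24)

    def test_pearson_matches_hand_formula(self):
        # frozen oracle computed from the centred-product formula and the
        # t-distribution with n-2 df
        pairs = [(1, 1.1), (2, 1.9), (3, 3.2), (4, 3.8), (5, 5.3), (6, 5.7),
                 (7, 7.2), (8, 7.9)]
        rep = inv.correlation_report(self._estimates(pairs), [(2, 3)])
        assert rep.loc[0, "pearson_r"] == pytest.approx(0.9960828621078925, rel=1e-12)
        assert rep.loc[0, "pearson_p"] == pytest.approx(1.4982000929455429e-07, rel=1e-6)

    def test_zero_variance_flagged(self):
        est = self._estimates([(1, 2), (2, 2), (3, 2), (4, 2)])
        rep = inv.correlation_report(est, [(2, 3)])
        assert bool(rep.loc[0, "undefined"]) and math.isnan(rep.loc[0, "pearson_r"])


class TestActivityToDose:
    def test_zero_activity(self):
        assert inv.activity_to_dose(0.0, 2) == 0.0

    def test_coefficients_increase_with_time(self):
        table = hx.presets.mean_dose_coefficients()
        assert table[14] > table[2]

    def test_day2_coefficient_arithmetic(self):
        # mean of the four measured dose/activity ratios at day 2
        expected = np.mean([1.31 / 5.74, 1.62 / 6.66, 2.16 / 7.65, 2.98 / 9.28])
        assert inv.activity_to_dose(1.0, 2) == pytest.approx(expected, rel=1e-12)

    def test_off_grid_day_requires_interpolation(self):
        with pytest.raises(ValueError):
            inv.activity_to_dose(5.0, 4)
        d3 = inv.activity_to_dose(5.0, 3)
        d5 = inv.activity_to_dose(5.0, 5)
        assert d3 < inv.activity_to_dose(5.0, 4, interpolate=True) < d5


class TestROC:
    def _estimates(self, scores, labels_high):
        return [
            inv.ActivityEstimate(
                time=2.0, measured_fluorescence=0.0, median_activity=s,
                min_activity=s, max_activity=s,
                true_activity=7.65 if high else 5.74,
            )
            for s, high in zip(scores, labels_high)
        ]

    def test_perfect_separation(self):
        est = self._estimates([1, 2, 3, 9, 10, 11], [0, 0, 0, 1, 1, 1])
        res = inv.classify_and_roc(est)
        assert res.auc == 1.0
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_identical_scores_give_half(self):
        est = self._estimates([5, 5, 5, 5, 5, 5], [0, 0, 0, 1, 1, 1])
        assert inv.classify_and_roc(est).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        est = self._estimates([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            inv.classify_and_roc(est)

    def test_threshold_sweep_equals_mann_whitney(self):
        # dual-computation oracle on tied, random score sets
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            auc_mw, _ = inv.delong_auc_variance(scores, labels)
            fpr, tpr, _ = roc_curve(labels, scores)
            auc_sweep = np.trapezoid(tpr, fpr)
            assert auc_mw == pytest.approx(auc_sweep, abs=1e-12)

    def test_roc_curve_monotone(self, noisy_fit, small_ensemble):
        points = [
            (t, hx.predict_fluorescence(noisy_fit.params, activity=a, time=t), a)
            for a in (5.74, 6.66, 7.65, 9.28)
            for t in (2.0, 3.0, 5.0)
        ]
        est = inv.summarize_estimates(small_ensemble, points)
        res = inv.classify_and_roc(est)
        assert np.all(np.diff(res.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(res.roc_points[:, 1]) >= 0)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
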