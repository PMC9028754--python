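"""Bump, cascade, WTA, mapping, and mismatch behavior of the analog model."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from gmmwake import analog as an
from gmmwake import pipeline as pl
from gmmwake import simulate as sim
from gmmwake.analog import (
    WTA_LOGICAL_ZERO,
    AnalogClassifierConfig,
    BumpParams,
    DeviceModel,
    FeatureScaler,
    MismatchSpec,
    apply_mismatch,
    bump_current,
    bump_shape,
    calibrate_width,
    class_current,
    classify_analog,
    classify_analog_batch,
    effective_sigma,
    map_gmm_to_analog,
    monte_carlo_eval,
    multivariate_bump,
    wta,
)
from gmmwake.features import FEATURE_COLUMNS
from gmmwake.gmm import ClassGMM, GaussianComponent, GMMClassifier, classify_batch


def gaussian_fit_r2(p, d, n_points=801):
    """Least-squares Gaussian fit quality over +-4 effective sigma."""
    s = effective_sigma(p, d)
    v = np.linspace(-4 * s, 4 * s, n_points)
    y = bump_shape(v + p.v_r, p, d)

    def g(x, a, sg):
        return a * np.exp(-(x**2) / (2 * sg**2))

    popt, _ = curve_fit(g, v, y, p0=[1.0, s])
    resid = y - g(v, *popt)
    return 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)


class TestBump:
    def test_peak_at_vr_equals_ibias(self, device):
        p = BumpParams(v_r=0.05, v_c=0.0, i_bias=12e-9)
        assert bump_current(0.05, p, device) == pytest.approx(12e-9 + device.leakage_floor)
        # strictly below peak anywhere else
        assert bump_current(0.06, p, device) < 12e-9

    def test_even_symmetry(self, device, rng):
        p = BumpParams(v_r=-0.02, v_c=0.05, i_bias=5e-9)
        for d in rng.uniform(0, 0.2, size=20):
            left = bump_current(p.v_r - d, p, device)
            right = bump_current(p.v_r + d, p, device)
            assert right == pytest.approx(left, rel=1e-12)

    def test_gaussian_fit_quality_across_vc_grid(self, device, calibration):
        for vc in calibration.vc_grid[::4]:
            r2 = gaussian_fit_r2(BumpParams(v_r=0.0, v_c=float(vc), i_bias=1.0), device)
            assert r2 > 0.99, f"R2={r2} at Vc={vc}"

    def test_peak_proportional_to_ibias(self, device):
        p1 = BumpParams(v_r=0.0, v_c=0.0, i_bias=1e-9)
        p2 = BumpParams(v_r=0.0, v_c=0.0, i_bias=4e-9)
        v = 0.03
        assert bump_current(v, p2, device) == pytest.approx(4 * bump_current(v, p1, device), rel=1e-12)

    def test_width_overflow_rejected(self):
        d = DeviceModel(width_c1=1e-6)  # exp overflow at ordinary Vc
        with pytest.raises(ValueError):
            d.width(0.3)


class TestCascade:
    def test_all_at_center_returns_first_bias(self, device, rng):
        cluster = [BumpParams(v_r=float(v), v_c=0.0, i_bias=12e-9 if n == 0 else 0.0)
                   for n, v in enumerate(rng.uniform(-0.1, 0.1, 4))]
        v_in = [p.v_r for p in cluster]
        assert multivariate_bump(v_in, cluster, device) == pytest.approx(12e-9, rel=1e-12)

    def test_one_far_dimension_kills_product(self, device):
        cluster = [BumpParams(v_r=0.0, v_c=0.0, i_bias=12e-9) for _ in range(4)]
        v_in = [0.0, 0.0, 0.25, 0.0]  # ~7 widths off center
        assert multivariate_bump(v_in, cluster, device) < 1e-12

    def test_closed_form_equals_sequential_cascade(self, device, rng):
        # oracle: explicitly bias each stage with its predecessor's output
        for _ in range(200):
            n = rng.integers(1, 7)
            cluster = [BumpParams(v_r=float(rng.uniform(-0.1, 0.1)),
                                  v_c=float(rng.uniform(-0.2, 0.2)),
                                  i_bias=float(rng.uniform(1e-10, 2e-8)) if k == 0 else 0.0)
                       for k in range(n)]
            v_in = rng.uniform(-0.15, 0.15, size=n)
            current = cluster[0].i_bias
            for k in range(n):
                stage = BumpParams(v_r=cluster[k].v_r, v_c=cluster[k].v_c, i_bias=current,
                                   width_gain=cluster[k].width_gain)
                current = bump_current(v_in[k], stage, device)
            assert multivariate_bump(v_in, cluster, device) == pytest.approx(current, rel=1e-9)

    def test_empty_cluster_rejected(self, device):
        with pytest.raises(ValueError):
            multivariate_bump([], [], device)


class TestClassCurrent:
    def test_single_cluster_reduces(self, device, rng):
        cluster = [BumpParams(v_r=0.0, v_c=0.0, i_bias=5e-9) for _ in range(3)]
        v = rng.uniform(-0.1, 0.1, 3)
        assert class_current(v, [cluster], device) == pytest.approx(
            multivariate_bump(v, cluster, device), rel=1e-12)

    def test_identical_clusters_double(self, device, rng):
        cluster = [BumpParams(v_r=0.02, v_c=0.0, i_bias=5e-9), BumpParams(v_r=-0.02, v_c=0.1)]
        v = rng.uniform(-0.1, 0.1, 2)
        one = class_current(v, [cluster], device)
        two = class_current(v, [cluster, cluster], device)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_sum_of_cluster_terms(self, device, rng):
        clusters = []
        for _ in range(3):
            clusters.append([
                BumpParams(v_r=float(rng.uniform(-0.1, 0.1)), v_c=float(rng.uniform(-0.1, 0.1)),
                           i_bias=float(rng.uniform(1e-9, 1e-8)) if n == 0 else 0.0)
                for n in range(2)
            ])
        v = rng.uniform(-0.1, 0.1, 2)
        expected = sum(multivariate_bump(v, cl, device) for cl in clusters)
        assert class_current(v, clusters, device) == pytest.approx(expected, rel=1e-12)


class TestWTA:
    def test_logical_one_and_zero(self):
        winner, out = wta([5e-9, 1e-9], wta_bias=12e-9)
        assert winner == 0
        assert out[0] == 12e-9
        assert out[1] < WTA_LOGICAL_ZERO

    def test_tie_goes_to_lowest_index(self):
        winner, out = wta([3e-9, 3e-9, 1e-9], wta_bias=12e-9)
        assert winner == 0

    def test_exactly_one_winner_and_losers_below_threshold(self, rng):
        for _ in range(50):
            cur = rng.uniform(0, 1e-8, size=rng.integers(2, 6))
            winner, out = wta(cur, wta_bias=12e-9)
            assert np.sum(out == 12e-9) == 1
            assert np.all(out[np.arange(out.size) != winner] < WTA_LOGICAL_ZERO)

    def test_permutation_equivariance(self, rng):
        for _ in range(50):
            cur = rng.uniform(0, 1e-8, size=4)
            cur += np.arange(4) * 1e-15  # break exact ties so permutation is well-defined
            perm = rng.permutation(4)
            w0, out0 = wta(cur, 12e-9)
            w1, out1 = wta(cur[perm], 12e-9)
            assert w1 == np.argwhere(perm == w0)[0, 0]
            np.testing.assert_array_equal(out1, out0[perm])

    def test_soft_mode_losers_still_logical_zero(self):
        _, out = wta([5e-9, 4.9e-9], wta_bias=12e-9, soft_gain=4.0)
        assert 0 < out[1] < WTA_LOGICAL_ZERO

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wta([], 12e-9)


class TestWidthCalibration:
    def test_forward_map_strictly_increasing(self, calibration):
        assert np.all(np.diff(calibration.sigma_grid) > 0)

    def test_roundtrip_within_one_percent(self, calibration):
        for sigma in np.linspace(calibration.sigma_grid[0] * 1.05,
                                 calibration.sigma_grid[-1] * 0.95, 7):
            vc = calibration.vc_of_sigma(sigma)
            assert calibration.sigma_of_vc(vc) == pytest.approx(sigma, rel=0.01)

    def test_out_of_range_clamps_with_warning(self, calibration):
        with pytest.warns(UserWarning, match="clamping"):
            vc = calibration.vc_of_sigma(10.0)
        assert vc == pytest.approx(calibration.vc_grid[-1])

    def test_non_monotone_width_law_rejected(self):
        d = DeviceModel(width_c1=-0.3)  # decreasing width law
        with pytest.raises(RuntimeError, match="non-monotone"):
            calibrate_width(d)


class TestMapping:
    def test_center_feature_maps_to_zero_volts(self, device, calibration):
        # symmetric scaler: feature range [0, 1] -> [-0.15, 0.15]
        scaler = FeatureScaler(gain=np.full(2, 0.3), offset=np.full(2, -0.15))
        comps = [GaussianComponent(mean=[0.5, 0.5], var=[0.01, 0.01], weight=1.0)]
        clf = GMMClassifier(classes=[ClassGMM(components=comps),
                                     ClassGMM(components=[GaussianComponent(
                                         mean=[0.2, 0.8], var=[0.01, 0.01], weight=1.0)])])
        cfg = map_gmm_to_analog(clf, device=device, scaler=scaler, calibration=calibration)
        for p in cfg.classes[0][0]:
            assert p.v_r == pytest.approx(0.0, abs=1e-12)

    def test_weight_ratio_preserved_untied(self, device, calibration):
        # equal variances so the normalization constants cancel
        mk = lambda m, w: GaussianComponent(mean=[m, m], var=[0.01, 0.01], weight=w)
        clf = GMMClassifier(classes=[
            ClassGMM(components=[mk(0.3, 0.7), mk(0.7, 0.3)]),
            ClassGMM(components=[mk(0.4, 0.5), mk(0.6, 0.5)]),
        ])
        scaler = FeatureScaler(gain=np.full(2, 0.3), offset=np.full(2, -0.15))
        cfg = map_gmm_to_analog(clf, device=device, scaler=scaler, calibration=calibration)
        b = [cl[0].i_bias for cl in cfg.classes[0]]
        assert b[0] / b[1] == pytest.approx(0.7 / 0.3, rel=1e-9)
        assert max(cl[0].i_bias for cls in cfg.classes for cl in cls) == pytest.approx(12e-9)

    def test_tied_weights_equal_within_class(self, day_scenario, device, calibration):
        scaler = FeatureScaler.from_data(day_scenario["train"][FEATURE_COLUMNS].to_numpy())
        cfg = map_gmm_to_analog(day_scenario["clf"], device=device, scaler=scaler,
                                calibration=calibration, tied_weights=True)
        for cls in cfg.classes:
            biases = [cl[0].i_bias for cl in cls]
            assert biases[0] == pytest.approx(biases[1], rel=1e-12)

    def test_config_roundtrip(self, mapped_analog, tmp_path):
        path = tmp_path / "analog.json"
        mapped_analog.save(path)
        back = AnalogClassifierConfig.load(path)
        X = np.asarray([[100e-6, 0.4, 0.15, 0.10]])
        np.testing.assert_array_equal(classify_analog_batch(X, back),
                                      classify_analog_batch(X, mapped_analog))
        assert back.wta_bias == mapped_analog.wta_bias


class TestAnalogClassification:
    def test_agreement_with_ideal_on_separated_data(self, day_scenario, mapped_analog):
        test = day_scenario["test"]
        X = test[FEATURE_COLUMNS].to_numpy()
        ideal = classify_batch(X, day_scenario["clf"])
        analog = classify_analog_batch(X, mapped_analog)
        assert np.mean(ideal == analog) >= 0.95

    def test_full_agreement_at_high_likelihood_ratio(self, day_scenario, mapped_analog):
        from gmmwake.gmm import log_mixture_pdf

        test = day_scenario["test"]
        X = test[FEATURE_COLUMNS].to_numpy()[:2000]
        clf = day_scenario["clf"]
        lr = np.array([log_mixture_pdf(x, clf.classes[0]) - log_mixture_pdf(x, clf.classes[1])
                       for x in X])
        confident = np.abs(lr) > np.log(10.0)
        ideal = classify_batch(X, clf)
        analog = classify_analog_batch(X, mapped_analog)
        assert confident.sum() > 100
        assert np.all(ideal[confident] == analog[confident])

    def test_deterministic(self, mapped_analog):
        x = [120e-6, 0.3, 0.2, 0.15]
        assert classify_analog(x, mapped_analog) == classify_analog(x, mapped_analog)

    def test_out_of_rail_input_clamps_with_warning(self, mapped_analog):
        x = np.array([1.0, 0.3, 0.2, 0.15])  # 1 Vpp is far outside the scaled range
        with pytest.warns(UserWarning, match="clamping"):
            classify_analog(x, mapped_analog)


class TestMismatch:
    def test_zero_sigma_is_identity(self, mapped_analog):
        spec = MismatchSpec(sigma_vr_offset=0, sigma_width_gain=0, sigma_current_gain=0,
                            n_runs=1, seed=0)
        pert = apply_mismatch(mapped_analog, spec, 0)
        for cls0, cls1 in zip(mapped_analog.classes, pert.classes):
            for cl0, cl1 in zip(cls0, cls1):
                for p0, p1 in zip(cl0, cl1):
                    assert p0 == p1

    def test_deterministic_given_seed_and_run(self, mapped_analog):
        spec = MismatchSpec(seed=5)
        a = apply_mismatch(mapped_analog, spec, 3)
        b = apply_mismatch(mapped_analog, spec, 3)
        assert a.classes[0][0][0].v_r == b.classes[0][0][0].v_r
        c = apply_mismatch(mapped_analog, spec, 4)
        assert a.classes[0][0][0].v_r != c.classes[0][0][0].v_r

    def test_perturbation_moments_match_spec(self, mapped_analog):
        spec = MismatchSpec(sigma_vr_offset=2e-3, sigma_width_gain=0.02,
                            sigma_current_gain=0.02, seed=11)
        n_bumps = 2 * 2 * 4
        deltas_vr, gains_w = [], []
        for r in range(10_000 // n_bumps + 1):
            pert = apply_mismatch(mapped_analog, spec, r)
            for cls0, cls1 in zip(mapped_analog.classes, pert.classes):
                for cl0, cl1 in zip(cls0, cls1):
                    for p0, p1 in zip(cl0, cl1):
                        deltas_vr.append(p1.v_r - p0.v_r)
                        gains_w.append(p1.width_gain / p0.width_gain - 1.0)
        assert np.std(deltas_vr) == pytest.approx(2e-3, rel=0.10)
        assert np.std(gains_w) == pytest.approx(0.02, rel=0.10)
        assert np.mean(deltas_vr) == pytest.approx(0.0, abs=3e-3 / np.sqrt(len(deltas_vr)) * 4)


class TestMonteCarlo:
    @staticmethod
    def _labeled_eval_data(day_scenario):
        test = day_scenario["test"]
        mask = test["state"].isin(pl.CLASS_LABELS)
        X = test[mask][FEATURE_COLUMNS].to_numpy()[:4000]
        y = np.where(test[mask]["state"] == "pre_ictal", 0, 1)[:4000]
        return X, y

    def test_zero_sigma_reproduces_unperturbed_specificity(self, day_scenario, mapped_analog):
        X, y = self._labeled_eval_data(day_scenario)
        spec = MismatchSpec(sigma_vr_offset=0, sigma_width_gain=0, sigma_current_gain=0,
                            n_runs=5, seed=0)
        runs, mean, std = monte_carlo_eval(mapped_analog, spec, X, y)
        pred = classify_analog_batch(X, mapped_analog)
        base = np.mean(pred[y == 1] == 1)
        assert std == 0.0
        assert all(r == base for r in runs)

    def test_run_count_and_range(self, day_scenario, mapped_analog):
        X, y = self._labeled_eval_data(day_scenario)
        runs, mean, std = monte_carlo_eval(mapped_analog, MismatchSpec(n_runs=12, seed=2), X, y)
        assert len(runs) == 12
        assert all(0.0 <= r <= 1.0 for r in runs)
        assert mean == pytest.approx(np.mean(runs))

    def test_spread_grows_with_sigma(self, device, calibration):
        # overlapping classes so mismatch actually moves the boundary
        rng = np.random.default_rng(0)
        mk = lambda m: ClassGMM(components=[GaussianComponent(
            mean=[m, m], var=[1.0, 1.0], weight=1.0)])
        clf = GMMClassifier(classes=[mk(-1.0), mk(1.0)])
        X = np.vstack([rng.normal(-1, 1, (400, 2)), rng.normal(1, 1, (400, 2))])
        y = np.repeat([0, 1], 400)
        scaler = FeatureScaler.from_data(X)
        cfg = map_gmm_to_analog(clf, device=device, scaler=scaler, calibration=calibration)
        stds_small, stds_big = [], []
        for seed in range(5):
            small = MismatchSpec(sigma_vr_offset=2e-3, sigma_width_gain=0.02,
                                 sigma_current_gain=0.02, n_runs=20, seed=seed)
            big = MismatchSpec(sigma_vr_offset=8e-3, sigma_width_gain=0.08,
                               sigma_current_gain=0.08, n_runs=20, seed=seed)
            stds_small.append(monte_carlo_eval(cfg, small, X, y)[2])
            stds_big.append(monte_carlo_eval(cfg, big, X, y)[2])
        assert np.mean(stds_big) >= np.mean(stds_small)

    def test_empty_data_rejected(self, mapped_analog):
        with pytest.raises(ValueError):
            monte_carlo_eval(mapped_analog, MismatchSpec(n_runs=1), np.empty((0, 4)), np.array([]))
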