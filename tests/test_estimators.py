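"""Univariable estimators against closed-form oracles and simulations."""

import numpy as np
import pytest

from causalmr import (
    SimConfig,
    harmonize,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
    mr_weighted_mode,
    simulate_two_sample,
    wald_ratios,
)
from causalmr.estimators import weighted_median

from conftest import make_hset, random_hset


class TestWaldRatios:
    def test_basic_ratio_and_se(self):
        h = make_hset([0.1], [0.01], [0.05], [0.01])
        r = wald_ratios(h)
        assert r.theta[0] == pytest.approx(0.5)
        assert r.sigma[0] == pytest.approx(0.1)

    def test_orientation_flips_pairs_jointly(self):
        h = make_hset([-0.1], [0.01], [0.05], [0.01])
        r = wald_ratios(h, orient=True)
        assert r.theta[0] == pytest.approx(-0.5)

    def test_theta_invariant_under_joint_sign_flip(self):
        h1 = make_hset([0.1, -0.2], [0.01] * 2, [0.05, 0.08], [0.01] * 2)
        h2 = make_hset([-0.1, 0.2], [0.01] * 2, [-0.05, -0.08], [0.01] * 2)
        np.testing.assert_allclose(wald_ratios(h1).theta, wald_ratios(h2).theta)

    def test_zero_beta_x_errors_with_variant_name(self):
        h = make_hset([0.1, 0.0], [0.01] * 2, [0.05, 0.01], [0.01] * 2)
        with pytest.raises(ValueError, match="rs2"):
            wald_ratios(h)


class TestIVW:
    def test_single_variant_is_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.01])
        est = mr_ivw(h)
        assert est.method == "wald_single"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_fixture_a_hand_values(self, fixture_a):
        est = mr_ivw(fixture_a, "fixed")
        # weights (100, 64, 144): beta = 112.8/308, se = 308^{-1/2}
        assert est.beta == pytest.approx(0.36623, abs=1e-5)
        assert est.se == pytest.approx(0.05698, abs=1e-5)

    def test_zero_heterogeneity_fixed_equals_random(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.04, 0.08], [0.01] * 2)
        assert mr_ivw(h, "fixed").se == pytest.approx(mr_ivw(h, "random").se)
        assert mr_ivw(h, "fixed").beta == pytest.approx(mr_ivw(h, "random").beta)

    def test_random_never_tighter_than_fixed(self, rng):
        for _ in range(20):
            h = random_hset(rng, k=10, alpha_sd=0.01)
            assert mr_ivw(h, "random").se >= mr_ivw(h, "fixed").se - 1e-15

    def test_equals_zero_intercept_wls(self, rng):
        """IVW beta is algebraically the slope of the weighted zero-intercept
        regression of beta_Y on beta_X with weights 1/se_Y^2."""
        for _ in range(25):
            h = random_hset(rng, k=15, alpha_sd=0.005)
            w = 1.0 / h.se_y**2
            bx = h.beta_x[:, 0]
            slope = np.sum(w * bx * h.beta_y) / np.sum(w * bx**2)
            assert mr_ivw(h).beta == pytest.approx(slope, abs=1e-10)

    def test_sign_equivariance(self, rng):
        h = random_hset(rng, k=10)
        h_neg = make_hset(-h.beta_x[:, 0], h.se_x[:, 0], h.beta_y, h.se_y)
        assert mr_ivw(h_neg).beta == pytest.approx(-mr_ivw(h).beta)


class TestEgger:
    def test_exact_affine_data_interpolated(self):
        bx = np.array([0.05, 0.10, 0.15])
        by = 0.01 + 0.4 * bx
        h = make_hset(bx, [0.01] * 3, by, [0.01] * 3)
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.4, abs=1e-10)
        assert intercept.beta == pytest.approx(0.01, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            k = 4
            bx = rng.uniform(0.05, 0.2, k)
            by = rng.normal(0.3 * bx, 0.01)
            sy = rng.uniform(0.005, 0.02, k)
            h = make_hset(bx, [0.01] * k, by, sy)
            slope, intercept = mr_egger(h)
            w = 1.0 / sy**2
            s_w, s_x = w.sum(), (w * bx).sum()
            s_xx, s_y, s_xy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
            det = s_w * s_xx - s_x**2
            a = (s_xx * s_y - s_x * s_xy) / det
            b = (s_w * s_xy - s_x * s_y) / det
            assert intercept.beta == pytest.approx(a, abs=1e-10)
            assert slope.beta == pytest.approx(b, abs=1e-10)

    def test_orientation_invariance(self, rng):
        h = random_hset(rng, k=8)
        bx, by = h.beta_x[:, 0].copy(), h.beta_y.copy()
        bx[0] *= -1
        by[0] *= -1
        h_flipped = make_hset(bx, h.se_x[:, 0], by, h.se_y)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(h_flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)

    def test_requires_three_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValueError, match=">=3"):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_middle_theta(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.02, 0.05, 0.09], [0.01] * 3)
        est = mr_weighted_median(h, nboot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_constant_ratios_recovered(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [1e-6] * 3)
        est = mr_weighted_median(h, nboot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.se < 1e-4

    def test_interpolation_formula(self):
        # unequal weights: hand-check the cumulative-weight interpolation
        theta = np.array([0.2, 0.5, 0.9])
        w = np.array([1.0, 1.0, 2.0])
        s = np.cumsum(w)
        p = (s - w / 2) / s[-1]
        want = np.interp(0.5, p, theta)
        assert weighted_median(theta, w) == pytest.approx(want)

    def test_robust_to_40pct_contamination(self):
        """With 40% of instruments carrying +0.5 pleiotropy the weighted
        median stays near truth while IVW is biased upward."""
        rng = np.random.default_rng(7)
        med_err, ivw_err = [], []
        theta = 0.3
        for rep in range(60):
            k = 20
            bx = rng.uniform(0.05, 0.15, k)
            sx = np.full(k, 0.002)
            sy = np.full(k, 0.002)  # strong-instrument regime: ratio noise ~0.02
            alpha = np.zeros(k)
            alpha[:8] = 0.5 * bx[:8]  # invalid 40%
            by = rng.normal(theta * bx + alpha, sy)
            h = make_hset(rng.normal(bx, sx), sx, by, sy)
            med_err.append(mr_weighted_median(h, nboot=2, seed=rep).beta - theta)
            ivw_err.append(mr_ivw(h).beta - theta)
        assert abs(np.median(med_err)) < 0.05
        assert np.median(ivw_err) > 0.1

    def test_bootstrap_bit_reproducible(self, fixture_a):
        a = mr_weighted_median(fixture_a, nboot=200, seed=42)
        b = mr_weighted_median(fixture_a, nboot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se


class TestWeightedMode:
    def test_constant_ratios_recovered(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        est = mr_weighted_mode(h, nboot=20, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_majority_cluster_wins(self, rng):
        theta_major = 0.30
        bx = rng.uniform(0.08, 0.2, 10)
        theta = np.array([theta_major + rng.normal(0, 0.005) for _ in range(7)]
                         + [0.80 + rng.normal(0, 0.005) for _ in range(3)])
        by = theta * bx
        h = make_hset(bx, [0.01] * 10, by, np.abs(bx) * 0.02)
        est = mr_weighted_mode(h, nboot=20, seed=0)
        assert est.beta == pytest.approx(theta_major, abs=0.03)

    def test_invariant_under_weight_rescaling(self, rng):
        """Doubling every instrument's weight rescales the kernel density
        without moving its argmax, so the estimate is unchanged."""
        h = random_hset(rng, k=8)
        h2 = make_hset(
            h.beta_x[:, 0], h.se_x[:, 0], h.beta_y, h.se_y / np.sqrt(2)
        )
        a = mr_weighted_mode(h, nboot=2, seed=1)
        b = mr_weighted_mode(h2, nboot=2, seed=1)
        assert a.beta == pytest.approx(b.beta, abs=1e-6)

    def test_requires_three_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValueError, match=">=3"):
            mr_weighted_mode(h)


class TestNullRecovery:
    def test_all_estimators_unbiased_without_pleiotropy(self):
        """Mean estimate over replicates within 3 Monte-Carlo SEs of truth."""
        theta = 0.365
        reps = 40
        results = {"ivw": [], "egger": [], "median": [], "mode": []}
        for i in range(reps):
            st = simulate_two_sample(SimConfig(k=50, theta=theta, seed=3000 + i))
            h = harmonize(st.exposure_tables, st.outcome_table, st.instrument_ids)
            results["ivw"].append(mr_ivw(h).beta)
            results["egger"].append(mr_egger(h)[0].beta)
            results["median"].append(mr_weighted_median(h, nboot=2, seed=i).beta)
            results["mode"].append(mr_weighted_mode(h, nboot=2, seed=i).beta)
        for name, vals in results.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - theta) < 3 * mc_se + 1e-9, name
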