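"""Estimators against closed-form oracles and invariance properties."""

import numpy as np
import pytest
import statsmodels.api as sm

from medimr.errors import InsufficientSnpsError, ValidationError
from medimr.estimators import (
    _weighted_median_point, all_methods, ivw, mode_estimate, mr_egger,
    wald_ratio, weighted_median,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_formula(self):
        ratio, se = wald_ratio(0.10, 0.01, 0.05, 0.02)
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        ratio, _ = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert ratio == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_single_snp_equals_wald_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        r = ivw(h, variant="fixed")
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_consensus_ratios_give_zero_q_and_equal_variants(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, [0.01] * 3, 0.4 * bx, [0.01, 0.02, 0.03])
        fixed = ivw(h, variant="fixed")
        mre = ivw(h, variant="mre")
        assert fixed.estimate == pytest.approx(0.4, abs=1e-14)
        assert mre.estimate == pytest.approx(0.4, abs=1e-14)
        assert mre.se == pytest.approx(fixed.se)  # Q = 0 -> no inflation

    def test_three_snp_closed_form_oracle(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.02, 0.05, 0.09])
        sy = np.array([0.01, 0.01, 0.01])
        h = make_harmonized(bx, [0.01] * 3, by, sy)
        w = 1 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx * bx)
        r = ivw(h, variant="fixed")
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_against_statsmodels_wls_through_origin(self, rng):
        bx = rng.normal(0.1, 0.03, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        h = make_harmonized(bx, np.full(8, 0.01), by, sy)
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        r_fixed = ivw(h, variant="fixed")
        r_mre = ivw(h, variant="mre")
        assert r_fixed.estimate == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels' bse uses the estimated residual scale = mre without floor
        assert r_mre.se == pytest.approx(max(r_fixed.se, fit.bse[0]), rel=1e-8)

    def test_mre_needs_two_snps(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientSnpsError):
            ivw(h, variant="mre")


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx  # exact line, all bx > 0
        h = make_harmonized(bx, [0.01] * 4, by, [0.01, 0.02, 0.01, 0.03])
        slope, intercept = mr_egger(h)
        assert slope.estimate == pytest.approx(0.5, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.02, abs=1e-12)

    def test_four_point_fixture_matches_statsmodels_wls(self, rng):
        bx = np.array([0.12, 0.25, 0.31, 0.44])
        by = np.array([0.03, 0.09, 0.11, 0.20])
        sy = np.array([0.01, 0.015, 0.012, 0.02])
        h = make_harmonized(bx, [0.01] * 4, by, sy)
        slope, intercept = mr_egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert intercept.estimate == pytest.approx(fit.params[0], abs=1e-10)
        assert slope.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.se == pytest.approx(fit.bse[0], rel=1e-8)
        assert slope.se == pytest.approx(fit.bse[1], rel=1e-8)
        assert slope.pval == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_orientation_flips_negative_exposure_rows(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.02 * np.sign(bx) + 0.5 * bx  # line after orientation
        h = make_harmonized(bx, [0.01] * 4, by, [0.01] * 4)
        slope, intercept = mr_egger(h)
        assert slope.estimate == pytest.approx(0.5, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.02, abs=1e-12)

    def test_needs_three_snps(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientSnpsError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_pick_middle_ratio(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.4, 0.9])
        h = make_harmonized(bx, [0.01] * 3, by, [0.02] * 3)
        r = weighted_median(h, n_boot=50, seed=1)
        assert r.estimate == pytest.approx(0.4)

    def test_dominant_weight_snaps_to_its_ratio(self):
        # weights 0.2/0.6/0.2 put the cumulative midpoint of the middle
        # ratio exactly at 0.5
        r = _weighted_median_point(
            np.array([0.1, 0.4, 0.9]), np.array([0.2, 0.6, 0.2])
        )
        assert r == pytest.approx(0.4)

    def test_five_snp_unequal_weights_match_brute_force(self, rng):
        bx = rng.uniform(0.05, 0.3, 5)
        by = rng.normal(0.3, 0.1, 5) * bx
        sy = rng.uniform(0.005, 0.03, 5)
        h = make_harmonized(bx, np.full(5, 0.01), by, sy)
        ratios = by / bx
        w = (bx / sy) ** 2
        w = w / w.sum()
        order = np.argsort(ratios)
        rs, ws = ratios[order], w[order]
        cums = np.cumsum(ws) - ws / 2
        expected = np.interp(0.5, cums, rs)
        r = weighted_median(h, n_boot=50, seed=1)
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_reproducible_under_seed(self):
        h = make_harmonized(
            [0.1, 0.2, 0.3, 0.15], [0.01] * 4,
            [0.03, 0.08, 0.13, 0.05], [0.01, 0.02, 0.015, 0.01],
        )
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        c = weighted_median(h, n_boot=200, seed=8)
        assert a.se == b.se
        assert a.se != c.se


class TestMode:
    def test_dominant_cluster_wins_over_outlier(self):
        bx = np.ones(4)
        by = np.array([0.2, 0.2, 0.2, 5.0])
        h = make_harmonized(bx, [0.01] * 4, by, [0.02] * 4)
        r = mode_estimate(h, weighted=False, n_boot=50, seed=1)
        assert r.estimate == pytest.approx(0.2, abs=0.05)

    def test_degenerate_equal_ratios_return_that_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, [0.01] * 3, 0.7 * bx, [0.02] * 3)
        r = mode_estimate(h, weighted=True, n_boot=50, seed=1)
        assert r.estimate == pytest.approx(0.7, abs=1e-9)

    def test_two_cluster_fixture_matches_dense_grid_argmax(self, rng):
        # weights deliberately favor the smaller cluster so simple and
        # weighted modes disagree
        bx = np.array([0.1, 0.11, 0.12, 0.3, 0.31])
        ratios = np.array([0.20, 0.21, 0.22, 0.60, 0.61])
        by = ratios * bx
        sy = np.array([0.02, 0.02, 0.02, 0.002, 0.002])
        h = make_harmonized(bx, np.full(5, 0.01), by, sy)

        def oracle(weighted):
            w = (bx / sy) ** 2 if weighted else np.ones(5)
            w = w / w.sum()
            sd = np.std(ratios, ddof=1)
            mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6744897501960817
            bw = 0.9 * min(sd, mad) * 5 ** (-0.2)
            grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 200_001)
            dens = (
                w[None, :]
                * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bw) ** 2)
            ).sum(axis=1)
            return grid[np.argmax(dens)]

        simple = mode_estimate(h, weighted=False, n_boot=20, seed=1)
        weighted = mode_estimate(h, weighted=True, n_boot=20, seed=1)
        assert simple.estimate == pytest.approx(oracle(False), abs=2e-3)
        assert weighted.estimate == pytest.approx(oracle(True), abs=2e-3)
        assert abs(simple.estimate - weighted.estimate) > 0.2

    def test_needs_three_snps(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientSnpsError):
            mode_estimate(h)


class TestInvariances:
    def _fixture(self, rng, J=6):
        bx = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
        by = 0.3 * bx + rng.normal(0, 0.01, J)
        sy = rng.uniform(0.005, 0.02, J)
        return bx, np.full(J, 0.01), by, sy

    def test_sign_equivariance(self, rng):
        bx, sx, by, sy = self._fixture(rng)
        base = all_methods(make_harmonized(bx, sx, by, sy), n_boot=50, seed=3)
        neg = all_methods(make_harmonized(-bx, sx, by, sy), n_boot=50, seed=3)
        for m in ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"):
            assert neg[m].estimate == pytest.approx(-base[m].estimate, abs=1e-9)
        # Egger intercept: recoding the exposure negates the oriented outcome
        # wholesale, so the intercept negates while its evidence is unchanged
        assert abs(neg["egger_intercept"].estimate) == pytest.approx(
            abs(base["egger_intercept"].estimate), abs=1e-12
        )
        assert neg["egger_intercept"].pval == pytest.approx(
            base["egger_intercept"].pval, abs=1e-12
        )

    def test_scale_equivariance(self, rng):
        bx, sx, by, sy = self._fixture(rng)
        c = 2.5
        base = all_methods(make_harmonized(bx, sx, by, sy), n_boot=0, seed=3)
        scaled = all_methods(make_harmonized(c * bx, sx, by, sy), n_boot=0, seed=3)
        for m in ("ivw", "egger"):
            assert scaled[m].estimate == pytest.approx(base[m].estimate / c, abs=1e-9)

    def test_median_and_mode_stay_within_ratio_range(self, rng):
        for _ in range(5):
            bx, sx, by, sy = self._fixture(rng)
            h = make_harmonized(bx, sx, by, sy)
            ratios = by / bx
            lo, hi = ratios.min(), ratios.max()
            for res in (
                weighted_median(h, n_boot=0, seed=1),
                mode_estimate(h, weighted=False, n_boot=0, seed=1),
                mode_estimate(h, weighted=True, n_boot=0, seed=1),
            ):
                assert lo - 1e-9 <= res.estimate <= hi + 1e-9

    def test_ci_brackets_estimate_and_or_fields_consistent(self, rng):
        bx, sx, by, sy = self._fixture(rng)
        res = all_methods(
            make_harmonized(bx, sx, by, sy), n_boot=30, seed=2, binary_outcome=True
        )
        for r in res.values():
            assert r.ci_low <= r.estimate <= r.ci_high
            assert r.or_point == pytest.approx(np.exp(r.estimate))
            assert r.or_low == pytest.approx(np.exp(r.ci_low))
            assert r.or_high == pytest.approx(np.exp(r.ci_high))
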