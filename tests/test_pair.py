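"""Drift coefficients, fixed points, phase portraits and rate scans."""

import numpy as np
import pytest
from dataclasses import replace

from stdpnet.experiments import REGIMES
from stdpnet.pair import (
    PairConfig,
    DriftCoefficients,
    drift_coefficients,
    fixed_points,
    phase_portrait,
    basin_fraction,
    rate_scan,
    simulate_pair,
    siegert_rate,
    siegert_bias_for_rate,
)

W_MAX = 2.0


def coeffs_for(regime: str, rate: float) -> DriftCoefficients:
    w = REGIMES[regime].window
    return drift_coefficients(PairConfig(r1=rate, r2=rate, window=w))


class TestSiegert:
    def test_inversion_round_trip(self, neuron):
        for r in (5.0, 20.0, 45.0):
            mu = siegert_bias_for_rate(r, neuron, 50.0)
            assert siegert_rate(mu, neuron, 50.0) == pytest.approx(r, rel=1e-6)

    def test_noise_free_limit_matches_closed_form(self, neuron):
        gap = neuron.v_thresh - neuron.v_rest
        mu = 14.0
        expected = 1000.0 / (neuron.tau_m * np.log(mu / (mu - gap)))
        assert siegert_rate(mu, neuron, 0.0) == pytest.approx(expected)


class TestDriftCoefficients:
    def test_balanced_symmetric_rates(self):
        c = coeffs_for("balanced", 20.0)
        assert c.gamma == pytest.approx(0.0, abs=1e-12)
        assert c.alpha == pytest.approx(c.beta, rel=1e-9)
        assert c.alpha > 0

    def test_potentiation_dominated_signs(self):
        c = coeffs_for("potentiation_dominant", 20.0)
        assert c.alpha > c.beta
        assert c.gamma > 0

    def test_depression_dominated_signs(self):
        c = coeffs_for("depression_dominant", 20.0)
        assert c.beta > c.alpha
        assert c.gamma < 0

    def test_rightward_shift_gamma_flips_sign_with_rate(self):
        low = coeffs_for("rightward_shifted", 20.0)
        high = coeffs_for("rightward_shifted", 50.0)
        assert low.gamma > 0
        assert high.gamma < 0

    def test_zero_rates_give_zero_coefficients(self):
        w = REGIMES["balanced"].window
        c = drift_coefficients(PairConfig(r1=0.0, r2=0.0, window=w))
        assert c.alpha == c.beta == c.gamma == 0.0

    def test_unequal_rates_give_per_synapse_coefficients(self):
        w = REGIMES["balanced"].window
        c = drift_coefficients(PairConfig(r1=20.0, r2=30.0, window=w))
        assert c.alpha12 != c.alpha21
        # chance-pairing term is symmetric for all-to-all pairing
        assert c.gamma12 == pytest.approx(c.gamma21)


class TestFixedPoints:
    def test_balanced_line_of_equilibria(self):
        c = coeffs_for("balanced", 20.0)
        [fp] = fixed_points(c, W_MAX)
        assert fp.kind == "line of equilibria"
        dx, dy = fp.line_direction
        assert dy / dx == pytest.approx(1.0, rel=1e-6)  # the diagonal w12 = w21
        assert fp.eigenvalues[1] > 0  # transversally unstable

    def test_potentiation_dominated_unstable_node_outside(self):
        c = coeffs_for("potentiation_dominant", 20.0)
        [fp] = fixed_points(c, W_MAX)
        assert fp.kind == "unstable node"
        assert fp.location[0] < 0 and fp.location[1] < 0
        assert not fp.inside
        # location solves the 2x2 linear system
        expected = c.gamma / (c.beta - c.alpha)
        assert fp.location[0] == pytest.approx(expected)

    def test_depression_dominated_saddle_outside(self):
        c = coeffs_for("depression_dominant", 20.0)
        [fp] = fixed_points(c, W_MAX)
        assert fp.kind == "saddle"
        assert fp.location[0] < 0
        assert not fp.inside

    def test_eigenstructure_of_symmetric_system(self):
        c = coeffs_for("depression_dominant", 20.0)
        J = c.jacobian()
        np.testing.assert_allclose(J @ [1, 1], (c.alpha - c.beta) * np.array([1, 1]))
        np.testing.assert_allclose(J @ [1, -1], (c.alpha + c.beta) * np.array([1, -1]))
        [fp] = fixed_points(c, W_MAX)
        assert fp.eigenvalues == pytest.approx(
            tuple(sorted((c.alpha - c.beta, c.alpha + c.beta)))
        )

    def test_unequal_rates_tilt_the_equilibrium_line(self):
        # balanced window, r1 != r2: still a line of equilibria (gamma = 0
        # exactly), but tilted off the diagonal toward the lower-rate neuron
        w = REGIMES["balanced"].window
        c = drift_coefficients(PairConfig(r1=20.0, r2=30.0, window=w))
        [fp] = fixed_points(c, W_MAX)
        assert fp.kind == "line of equilibria"
        dx, dy = fp.line_direction
        assert dx > 0 and dy > 0
        assert dy / dx != pytest.approx(1.0, rel=1e-3)
        # the line direction is the null vector of the Jacobian
        residual = c.jacobian() @ np.array([dx, dy])
        assert np.abs(residual).max() < 1e-12

    def test_singular_inconsistent_system_has_no_fixed_point(self):
        c = DriftCoefficients(alpha12=1.0, beta12=1.0, gamma12=0.5,
                              alpha21=1.0, beta21=1.0, gamma21=0.5)
        assert fixed_points(c, W_MAX) == []


class TestPhasePortrait:
    def test_balanced_off_diagonal_start_reaches_unidirectional_corner(self):
        c = coeffs_for("balanced", 20.0)
        from stdpnet.pair import _integrate_to_attractor
        end = _integrate_to_attractor(c, 0.6 * W_MAX, 0.4 * W_MAX, W_MAX)
        assert end is not None
        assert end[0] == pytest.approx(W_MAX, abs=0.02 * W_MAX)
        assert end[1] == pytest.approx(0.0, abs=0.02 * W_MAX)

    def test_balanced_diagonal_start_stays_at_equilibrium(self):
        c = coeffs_for("balanced", 20.0)
        from stdpnet.pair import _integrate_to_attractor
        end = _integrate_to_attractor(c, 0.3 * W_MAX, 0.3 * W_MAX, W_MAX)
        assert end == pytest.approx((0.3 * W_MAX, 0.3 * W_MAX))

    def test_balanced_portrait_has_line_plus_two_corners(self):
        c = coeffs_for("balanced", 20.0)
        p = phase_portrait(c, W_MAX, grid_n=13)
        assert p.n_unresolved == 0
        assert "equilibrium line" in p.attractors
        assert (W_MAX, 0.0) in p.attractors and (0.0, W_MAX) in p.attractors
        assert (0.0, 0.0) not in p.attractors and (W_MAX, W_MAX) not in p.attractors

    def test_potentiation_dominated_three_basins(self):
        c = coeffs_for("potentiation_dominant", 20.0)
        p = phase_portrait(c, W_MAX, grid_n=13)
        pts = [a for a in p.attractors if not isinstance(a, str)]
        assert set(pts) == {(W_MAX, W_MAX), (W_MAX, 0.0), (0.0, W_MAX)}

    def test_depression_dominated_has_origin_attractor(self):
        c = coeffs_for("depression_dominant", 20.0)
        p = phase_portrait(c, W_MAX, grid_n=13)
        pts = [a for a in p.attractors if not isinstance(a, str)]
        assert (0.0, 0.0) in pts
        assert (W_MAX, W_MAX) not in pts

    def test_basin_fractions_sum_to_one(self):
        c = coeffs_for("potentiation_dominant", 20.0)
        p = phase_portrait(c, W_MAX, grid_n=13)
        total = sum(basin_fraction(p, a) for a in p.attractors)
        total += p.n_unresolved / p.labels.size
        assert total == pytest.approx(1.0)

    def test_single_attractor_portrait_has_fraction_one(self):
        c = coeffs_for("rightward_shifted", 50.0)
        p = phase_portrait(c, W_MAX, grid_n=9)
        assert basin_fraction(p, (0.0, 0.0)) == pytest.approx(1.0)

    def test_unknown_attractor_rejected(self):
        c = coeffs_for("balanced", 20.0)
        p = phase_portrait(c, W_MAX, grid_n=5)
        with pytest.raises(ValueError):
            basin_fraction(p, (0.5 * W_MAX, 0.123 * W_MAX))


class TestRateScan:
    def test_depression_dominated_has_no_stable_positive_interval(self):
        w = REGIMES["depression_dominant"].window
        cfg = PairConfig(r1=20, r2=20, window=w)
        res = rate_scan(w, cfg, np.arange(5.0, 55.0, 2.5))
        assert res.stable_interval is None

    def test_small_shift_has_no_stable_positive_interval(self):
        w = replace(REGIMES["rightward_shifted"].window, shift=2.0)
        cfg = PairConfig(r1=20, r2=20, window=w)
        res = rate_scan(w, cfg, np.arange(5.0, 55.0, 2.5))
        assert res.stable_interval is None

    def test_band_endpoints_vary_continuously_with_shift(self):
        # the homeostatic band should not jump as the shift changes slightly
        uppers = []
        for shift in (10.0, 10.5, 11.0):
            w = replace(REGIMES["rightward_shifted"].window, shift=shift)
            res = rate_scan(w, PairConfig(r1=20, r2=20, window=w),
                            np.arange(30.0, 50.5, 0.5))
            assert res.stable_interval is not None
            uppers.append(res.stable_interval[1])
        # upper edge drifts down smoothly as the shift deepens the notch
        assert uppers[0] >= uppers[1] >= uppers[2]
        assert uppers[0] - uppers[2] < 4.0

    def test_ascending_rates_required(self):
        w = REGIMES["rightward_shifted"].window
        with pytest.raises(ValueError):
            rate_scan(w, PairConfig(r1=20, r2=20, window=w), [30.0, 10.0])


class TestSimulatePair:
    def test_zero_rates_zero_weights_drift_is_zero(self):
        w = REGIMES["balanced"].window
        cfg = PairConfig(r1=0.0, r2=0.0, window=w)
        est = simulate_pair(cfg, 0.0, 0.0, duration=5.0, seed=0)
        assert est.drift12 == 0.0 and est.drift21 == 0.0

    def test_balanced_equal_weights_drift_symmetrically(self):
        w = REGIMES["balanced"].window
        cfg = PairConfig(r1=20.0, r2=20.0, window=w)
        est = simulate_pair(cfg, 1.0, 1.0, duration=120.0, seed=7)
        # same-seed noise makes the two synapses statistically exchangeable
        assert abs(est.drift12 - est.drift21) < 3 * (est.se12 + est.se21)

    def test_out_of_bounds_weights_rejected(self):
        w = REGIMES["balanced"].window
        cfg = PairConfig(r1=20.0, r2=20.0, window=w)
        with pytest.raises(ValueError):
            simulate_pair(cfg, -0.1, 0.0, duration=1.0)
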