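"""LIF network simulator: integration accuracy, determinism, plasticity."""

import math

import numpy as np
import pytest
from dataclasses import replace

from stdpnet.network import (
    NeuronParams,
    NetworkParams,
    WeightMatrix,
    SteadyStateRecord,
    initial_weights,
    simulate,
    calibrate_bias,
    CalibrationError,
    detect_steady_state,
)
from stdpnet.window import STDPWindow, Pairing, pair_spikes, window_value

FROZEN = STDPWindow(a_plus=1e-9, a_minus=1e-9, tau_plus=20, tau_minus=20)


def tiny_params(**kw):
    defaults = dict(
        n_exc=3,
        n_inh=1,
        mu=0.0,
        sigma=0.0,
        seed=0,
        fixed_bounds={"ei": 1e-12, "ie": 1e-12, "ii": 1e-12},
        w_max_ee=2.0,
    )
    defaults.update(kw)
    return NetworkParams(**defaults)


def zero_weights(n=3, w_max=2.0):
    return WeightMatrix(entries=np.zeros((n, n)), w_max=w_max)


class TestMembraneIntegration:
    def test_subthreshold_bias_produces_no_spikes(self, neuron):
        params = tiny_params(mu=5.0)  # gap is 10 mV
        raster, _, _ = simulate(params, neuron, FROZEN, zero_weights(), 1000.0,
                                plasticity=False)
        assert raster.times.size == 0

    def test_suprathreshold_isi_matches_closed_form(self, neuron):
        # ISI = tau_m * ln(mu / (mu - gap)) for noise-free, input-free LIF
        mu = 14.0
        gap = neuron.v_thresh - neuron.v_rest
        params = tiny_params(mu=mu, dt=0.1)
        raster, _, _ = simulate(params, neuron, FROZEN, zero_weights(), 3000.0,
                                plasticity=False)
        isi = np.diff(raster.train(0))
        expected = neuron.tau_m * math.log(mu / (mu - gap))
        assert isi.mean() == pytest.approx(expected, rel=0.005)

    def test_halving_dt_does_not_change_closed_form_agreement(self, neuron):
        mu = 14.0
        gap = neuron.v_thresh - neuron.v_rest
        expected = neuron.tau_m * math.log(mu / (mu - gap))
        for dt in (0.1, 0.05):
            params = tiny_params(mu=mu, dt=dt)
            raster, _, _ = simulate(params, neuron, FROZEN, zero_weights(), 3000.0,
                                    plasticity=False)
            isi = np.diff(raster.train(0))
            assert isi.mean() == pytest.approx(expected, rel=0.005)


class TestContracts:
    def test_plasticity_off_returns_initial_weights_bit_exact(self, neuron, rng):
        params = tiny_params(n_exc=5, mu=12.0, sigma=10.0, seed=3,
                             fixed_bounds={"ei": 0.5, "ie": 1.0, "ii": 1.0})
        init = initial_weights(params, rng)
        window = STDPWindow(a_plus=0.01, a_minus=0.01, tau_plus=20, tau_minus=20)
        _, weights, _ = simulate(params, neuron, window, init, 500.0, plasticity=False)
        np.testing.assert_array_equal(weights.entries, init.entries)

    def test_seed_determinism(self, neuron):
        params = tiny_params(n_exc=4, mu=11.0, sigma=15.0, seed=9,
                             fixed_bounds={"ei": 0.5, "ie": 1.0, "ii": 1.0})
        init = initial_weights(params)
        window = STDPWindow(a_plus=0.02, a_minus=0.02, tau_plus=20, tau_minus=20)
        r1, w1, _ = simulate(params, neuron, window, init, 800.0)
        r2, w2, _ = simulate(params, neuron, window, init, 800.0)
        np.testing.assert_array_equal(r1.times, r2.times)
        np.testing.assert_array_equal(r1.ids, r2.ids)
        np.testing.assert_array_equal(w1.entries, w2.entries)

    def test_noise_free_spike_count_invariant_across_runs(self, neuron):
        params = tiny_params(mu=13.0, sigma=0.0)
        counts = set()
        for _ in range(3):
            raster, _, _ = simulate(params, neuron, FROZEN, zero_weights(), 1000.0,
                                    plasticity=False)
            counts.add(raster.times.size)
        assert len(counts) == 1

    def test_invalid_inputs_rejected(self, neuron):
        params = tiny_params(mu=10.0)
        with pytest.raises(ValueError):
            simulate(params, neuron, FROZEN, zero_weights(), -5.0)
        with pytest.raises(ValueError):
            simulate(params, neuron, FROZEN, zero_weights(n=7), 100.0)

    @pytest.mark.parametrize("pairing,shift,a_minus", [
        (Pairing.ALL_TO_ALL, 0.0, 0.1),
        (Pairing.NEAREST_NEIGHBOR, 10.0, 0.0568),
    ])
    def test_weight_bounds_never_violated(self, neuron, pairing, shift, a_minus):
        window = STDPWindow(a_plus=0.1, a_minus=a_minus, tau_plus=20, tau_minus=20,
                            shift=shift, pairing=pairing, w_max=0.3)
        params = tiny_params(n_exc=6, mu=13.0, sigma=20.0, seed=5, w_max_ee=0.3,
                             fixed_bounds={"ei": 0.5, "ie": 1.0, "ii": 1.0})
        rng = np.random.default_rng(0)
        init = WeightMatrix(entries=np.clip(rng.uniform(0, 0.3, (6, 6)), 0, 0.3) * (1 - np.eye(6)),
                            w_max=0.3)
        _, weights, _ = simulate(params, neuron, window, init, 3000.0)
        assert weights.entries.min() >= 0.0
        assert weights.entries.max() <= 0.3
        assert not weights.entries.diagonal().any()


class TestOfflineOnlineEquivalence:
    """The online traces/registers must reproduce offline pair accumulation."""

    @pytest.mark.parametrize("pairing,shift,a_minus_fac", [
        (Pairing.ALL_TO_ALL, 0.0, 1.0),
        (Pairing.NEAREST_NEIGHBOR, 0.0, 1.0),
        (Pairing.NEAREST_NEIGHBOR, 10.0, 0.568),
        (Pairing.NEAREST_NEIGHBOR, -10.0, 1.0 / 0.568),
    ])
    def test_online_weight_change_matches_offline_accumulation(
        self, neuron, pairing, shift, a_minus_fac
    ):
        # amplitudes tiny so no weight ever reaches a bound: the online
        # (clipped per event) and offline (unclipped sum) paths then agree
        a0 = 1e-6
        window = STDPWindow(a_plus=a0, a_minus=a0 * a_minus_fac, tau_plus=20,
                            tau_minus=20, shift=shift, pairing=pairing, w_max=2.0)
        params = tiny_params(n_exc=4, mu=12.0, sigma=15.0, seed=21,
                             fixed_bounds={"ei": 0.5, "ie": 1.0, "ii": 1.0})
        rng = np.random.default_rng(2)
        entries = rng.uniform(0.5, 1.5, (4, 4)) * (1 - np.eye(4))
        init = WeightMatrix(entries=entries, w_max=2.0)
        raster, weights, _ = simulate(params, neuron, window, init, 2000.0)
        online = weights.entries - init.entries
        for post in range(4):
            for pre in range(4):
                if pre == post:
                    continue
                offline = sum(
                    window_value(ev.dt, window)
                    for ev in pair_spikes(raster.train(pre), raster.train(post), pairing)
                )
                assert online[post, pre] == pytest.approx(offline, rel=1e-9, abs=1e-15)


class TestCalibration:
    def test_calibrated_bias_hits_target_rate(self, neuron):
        params = NetworkParams(n_exc=40, n_inh=40, seed=2)
        init = initial_weights(params)
        mu = calibrate_bias(params, neuron, target_rate=20.0, tolerance=1.0,
                            probe_duration=3000.0, init=init)
        probe = replace(params, mu=mu)
        raster, _, _ = simulate(probe, neuron, FROZEN, init, 3000.0, plasticity=False)
        assert raster.mean_rate("exc", t_start=750.0) == pytest.approx(20.0, abs=2.0)

    def test_bias_monotone_in_target_rate(self, neuron):
        params = NetworkParams(n_exc=40, n_inh=40, seed=2)
        init = initial_weights(params)
        mu20 = calibrate_bias(params, neuron, 20.0, tolerance=1.5, probe_duration=2000.0, init=init)
        mu30 = calibrate_bias(params, neuron, 30.0, tolerance=1.5, probe_duration=2000.0, init=init)
        assert mu30 > mu20

    def test_unattainable_target_raises(self, neuron):
        params = NetworkParams(n_exc=20, n_inh=20, seed=2)
        with pytest.raises(CalibrationError):
            calibrate_bias(params, neuron, target_rate=0.0)
        with pytest.raises(CalibrationError):
            calibrate_bias(params, neuron, target_rate=1e6)


class TestSteadyStateDetection:
    def _record(self, rates, w_mean, w_var, dt_s=1.0):
        t = np.arange(len(rates), dtype=float) * dt_s * 1000.0
        return SteadyStateRecord(times=t, rates=np.asarray(rates, float),
                                 w_mean=np.asarray(w_mean, float),
                                 w_var=np.asarray(w_var, float))

    def test_constant_series_converges_at_first_window(self):
        n = 50
        rec = self._record([20.0] * n, [0.25] * n, [0.02] * n)
        ok, t = detect_steady_state(rec, window_s=10.0, slope_tol=0.05)
        assert ok
        assert t == pytest.approx(10_000.0)

    def test_growing_mean_weight_is_not_steady(self):
        n = 50
        rec = self._record([20.0] * n, np.linspace(0.1, 0.9, n), [0.02] * n)
        ok, _ = detect_steady_state(rec, window_s=10.0, slope_tol=0.05)
        assert not ok

    def test_short_record_rejected(self):
        rec = self._record([20.0] * 5, [0.25] * 5, [0.02] * 5)
        with pytest.raises(ValueError):
            detect_steady_state(rec, window_s=10.0)


class TestIO:
    def test_raster_and_weights_round_trip(self, tmp_path, neuron, rng):
        params = tiny_params(n_exc=4, mu=12.0, sigma=10.0, seed=1,
                             fixed_bounds={"ei": 0.5, "ie": 1.0, "ii": 1.0})
        init = initial_weights(params, rng)
        raster, weights, _ = simulate(params, neuron, FROZEN, init, 400.0, plasticity=False)
        raster.to_csv(tmp_path / "raster.csv")
        weights.to_csv(tmp_path / "w.csv")
        from stdpnet.network import SpikeRaster
        r2 = SpikeRaster.from_csv(tmp_path / "raster.csv", duration=400.0, n_exc=4, n_inh=1)
        np.testing.assert_allclose(r2.times, raster.times)
        w2 = WeightMatrix.from_csv(tmp_path / "w.csv")
        np.testing.assert_allclose(w2.entries, weights.entries)
        assert w2.w_max == weights.w_max
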