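{
  "_notes": {
    "summary": "Reference configuration of the plastic recurrent-network model. Amplitudes are at the reference learning rate; network experiments multiply them by run.lr_scale, which rescales the speed of the weight dynamics without moving fixed points.",
    "neuron": "LIF with reset to rest; threshold gap 10 mV; membrane 20 ms.",
    "network": "All-to-all, no self-connections; non-plastic blocks uniform on [0, bound]; inhibition stronger than excitation (balanced state); sigma chosen for ISI CV ~ 1 near 20 Hz.",
    "stdp": "Per-regime windows live in stdpnet.experiments.REGIMES; this block holds the balanced reference. The rightward/leftward shifted windows use shift = +/-10 ms with a_minus/a_plus = 0.568, fixed by requiring the chance-pairing drift to change sign at 40 Hz; the dominant regimes tip the amplitude balance by 1.2%, the largest tip preserving three basins of attraction at 20-50 Hz.",
    "run": "Desk scale 0.4 of the 500+500 reference network."
  },
  "neuron": {
    "tau_m": 20.0,
    "v_rest": -60.0,
    "v_thresh": -50.0
  },
  "network": {
    "n_exc": 500,
    "n_inh": 500,
    "tau_s": 5.0,
    "w_max_ee": 2.0,
    "fixed_bounds": {"ei": 2.0, "ie": 6.0, "ii": 6.0},
    "sigma": 40.0,
    "dt": 0.1
  },
  "stdp": {
    "a_plus": 0.005,
    "a_minus": 0.005,
    "tau_plus": 20.0,
    "tau_minus": 20.0,
    "shift_ms": 0.0,
    "pairing": "all_to_all",
    "w_max": 2.0
  },
  "run": {
    "scale": 0.4,
    "lr_scale": 8.0,
    "duration_s": 200.0,
    "initial_rate_hz": 20.0
  }
}
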