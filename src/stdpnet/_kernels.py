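"""Numba inner loops for the LIF network simulator.

The kernel integrates the membrane equation with forward Euler and
Euler-Maruyama noise, propagates spikes with a one-step axonal latency, and
applies pair-based STDP to the excitatory-to-excitatory block online:
all-to-all interactions through exponentially decaying pre/post trace
variables, nearest-neighbor interactions through last-spike-time registers.
Both implementations reproduce the offline accumulation of
``window_value`` over ``pair_spikes`` of the recorded raster to floating
point tolerance (bounds permitting); this equivalence is enforced by tests.
"""

import numpy as np
from numba import njit

__all__ = ["run_lif_network"]


@njit(inline="always")
def _wval(dt, a_plus, a_minus, tau_p, tau_d, shift):
    if dt > shift:
        return a_plus * np.exp(-(dt - shift) / tau_p)
    elif dt < shift:
        return -a_minus * np.exp((dt - shift) / tau_d)
    elif shift == 0.0:
        return 0.0
    return a_plus


@njit(cache=False)
def run_lif_network(
    n_e,
    n_i,
    dt,
    n_steps,
    tau_m,
    v_rest,
    v_th,
    v_reset,
    tau_s,
    W,              # (n, n) weight magnitudes, entry (i, j) = synapse j -> i
    mu,             # (n,) external bias per neuron, mV
    sigma,          # white-noise amplitude, mV * sqrt(ms)
    plastic,        # 0/1: STDP on E->E block
    apply_updates,  # 0/1: 1 = modify W, 0 = only accumulate drift
    a_plus,
    a_minus,
    tau_p,
    tau_d,
    shift,
    w_max_ee,
    nearest,        # 0 = all-to-all traces, 1 = nearest-neighbor registers
    seed,
    sample_every,   # steps between statistic samples (>= 1)
    max_spikes,     # capacity of the spike record
):
    np.random.seed(seed)
    n = n_e + n_i
    v = v_rest + (v_th - v_rest) * np.random.random(n)
    I = np.zeros(n)
    dec_s = np.exp(-dt / tau_s)
    dec_p = np.exp(-dt / tau_p)
    dec_d = np.exp(-dt / tau_d)
    noise_fac = (sigma / tau_m) * np.sqrt(dt)
    leak_fac = dt / tau_m

    xp = np.zeros(n_e)  # presynaptic (potentiation) traces
    xd = np.zeros(n_e)  # postsynaptic (depression) traces
    tlast = np.full(n_e, -1.0e12)

    spk_t = np.empty(max_spikes)
    spk_id = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0
    overflowed = False

    prev = np.empty(n, dtype=np.int64)
    n_prev = 0
    cur = np.empty(n, dtype=np.int64)
    spiking_now = np.zeros(n_e, dtype=np.bool_)

    # drift accumulator for frozen-weight runs (pair analysis)
    dacc = np.zeros((n_e, n_e)) if apply_updates == 0 else np.zeros((1, 1))

    n_samples = n_steps // sample_every
    samp_t = np.empty(n_samples)
    samp_rate = np.empty(n_samples)
    samp_wmean = np.empty(n_samples)
    samp_wvar = np.empty(n_samples)
    samp_d01 = np.empty(n_samples)
    samp_d10 = np.empty(n_samples)
    e_spikes_in_bin = 0
    i_sample = 0

    ee_off = n_e * n_e - n_e  # number of off-diagonal E->E entries

    for step in range(n_steps):
        t = step * dt
        # synaptic input: exponential decay plus last step's arrivals
        for i in range(n):
            I[i] *= dec_s
        for s in range(n_prev):
            j = prev[s]
            if j < n_e:
                for i in range(n):
                    I[i] += W[i, j]
            else:
                for i in range(n):
                    I[i] -= W[i, j]

        # membrane update (Euler-Maruyama), then threshold/reset
        n_cur = 0
        for i in range(n):
            v[i] += leak_fac * ((v_rest - v[i]) + I[i] + mu[i]) + noise_fac * np.random.normal()
            if v[i] >= v_th:
                v[i] = v_reset
                cur[n_cur] = i
                n_cur += 1
                if n_spk < max_spikes:
                    spk_t[n_spk] = t
                    spk_id[n_spk] = i
                    n_spk += 1
                else:
                    overflowed = True
                if i < n_e:
                    e_spikes_in_bin += 1

        if plastic == 1:
            for s in range(n_cur):
                k = cur[s]
                if k < n_e:
                    spiking_now[k] = True
            if nearest == 0:
                # all-to-all via traces; one aggregated update per spike
                for s in range(n_cur):
                    k = cur[s]
                    if k >= n_e:
                        continue
                    for j in range(n_e):
                        if j == k:
                            continue
                        dw_in = a_plus * xp[j]    # incoming j->k potentiation
                        dw_out = -a_minus * xd[j]  # outgoing k->j depression
                        if apply_updates == 1:
                            w1 = W[k, j] + dw_in
                            W[k, j] = min(w_max_ee, max(0.0, w1))
                            w2 = W[j, k] + dw_out
                            W[j, k] = min(w_max_ee, max(0.0, w2))
                        else:
                            dacc[k, j] += dw_in
                            dacc[j, k] += dw_out
            else:
                # nearest-neighbor via last-spike registers
                for s in range(n_cur):
                    k = cur[s]
                    if k >= n_e:
                        continue
                    for j in range(n_e):
                        if j == k:
                            continue
                        tl = t if spiking_now[j] else tlast[j]
                        if tl < -1.0e11:
                            continue
                        # spike of k as postsynaptic partner of synapse j->k
                        dw_in = _wval(t - tl, a_plus, a_minus, tau_p, tau_d, shift)
                        # spike of k as presynaptic partner of synapse k->j
                        dw_out = _wval(tl - t, a_plus, a_minus, tau_p, tau_d, shift)
                        if spiking_now[j] and j < k:
                            continue  # the coincident pair is handled once, by the smaller index
                        if apply_updates == 1:
                            w1 = W[k, j] + dw_in
                            W[k, j] = min(w_max_ee, max(0.0, w1))
                            w2 = W[j, k] + dw_out
                            W[j, k] = min(w_max_ee, max(0.0, w2))
                        else:
                            dacc[k, j] += dw_in
                            dacc[j, k] += dw_out
            # register/trace updates after all pairings of this step
            for s in range(n_cur):
                k = cur[s]
                if k < n_e:
                    xp[k] += 1.0
                    xd[k] += 1.0
                    tlast[k] = t
                    spiking_now[k] = False

        for j in range(n_e):
            xp[j] *= dec_p
            xd[j] *= dec_d

        n_prev = n_cur
        for s in range(n_cur):
            prev[s] = cur[s]

        if (step + 1) % sample_every == 0 and i_sample < n_samples:
            samp_t[i_sample] = (step + 1) * dt
            bin_ms = sample_every * dt
            samp_rate[i_sample] = e_spikes_in_bin / n_e / bin_ms * 1000.0
            e_spikes_in_bin = 0
            m = 0.0
            vv = 0.0
            if ee_off > 0:
                for a in range(n_e):
                    for b in range(n_e):
                        if a != b:
                            m += W[a, b]
                m /= ee_off
                for a in range(n_e):
                    for b in range(n_e):
                        if a != b:
                            d = W[a, b] - m
                            vv += d * d
                vv /= ee_off
            samp_wmean[i_sample] = m
            samp_wvar[i_sample] = vv
            if apply_updates == 0 and n_e >= 2:
                samp_d01[i_sample] = dacc[0, 1]
                samp_d10[i_sample] = dacc[1, 0]
            else:
                samp_d01[i_sample] = 0.0
                samp_d10[i_sample] = 0.0
            i_sample += 1

    return (
        spk_t[:n_spk],
        spk_id[:n_spk],
        overflowed,
        samp_t[:i_sample],
        samp_rate[:i_sample],
        samp_wmean[:i_sample],
        samp_wvar[:i_sample],
        samp_d01[:i_sample],
        samp_d10[:i_sample],
        dacc,
    )
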