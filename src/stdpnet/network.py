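"""Recurrent LIF network with plastic excitatory-to-excitatory synapses.

The membrane potential of each neuron follows

    tau_m dV/dt = -(V - V_rest) + I(t),

with an instantaneous reset to ``V_rest`` at threshold.  The input ``I``
(measured in mV; the membrane resistance is absorbed) is the sum of a
synaptic term that jumps by the synaptic weight at each presynaptic arrival
and decays with ``tau_s`` in between, a constant external bias ``mu`` and
independent Gaussian white noise of amplitude ``sigma``.

Connectivity is all-to-all without self-connections.  The E->I, I->E and
I->I blocks are fixed, drawn uniformly on ``[0, bound]`` at initialization
(the two inhibitory-source bounds are equal, and inhibition is stronger than
excitation so the network settles into an asynchronous irregular balanced
state).  Only the E->E block is plastic, driven by the pair-based STDP
window of :mod:`stdpnet.window` under hard bounds ``[0, w_max_ee]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import run_lif_network
from .window import STDPWindow, Pairing

__all__ = [
    "NeuronParams",
    "NetworkParams",
    "WeightMatrix",
    "SpikeRaster",
    "SteadyStateRecord",
    "initial_weights",
    "simulate",
    "calibrate_bias",
    "CalibrationError",
    "detect_steady_state",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants.  Reset equals rest, per the network model."""

    tau_m: float = 20.0    # ms
    v_rest: float = -60.0  # mV
    v_thresh: float = -50.0  # mV

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_thresh <= self.v_rest:
            raise ValueError("v_thresh must exceed v_rest")

    @property
    def v_reset(self) -> float:
        return self.v_rest


@dataclass(frozen=True)
class NetworkParams:
    """Population sizes, synaptic constants and external drive.

    ``fixed_bounds`` are the upper limits of the uniform initialization of
    the non-plastic blocks, keyed ``"ei"`` (E onto I), ``"ie"`` (I onto E)
    and ``"ii"`` (I onto I); the two inhibitory-source bounds must be equal.
    ``mu`` may be a scalar (same bias for every neuron) or a length
    ``n_exc + n_inh`` array.
    """

    n_exc: int = 500
    n_inh: int = 500
    tau_s: float = 5.0          # ms
    w_max_ee: float = 2.0       # mV
    fixed_bounds: dict = field(
        default_factory=lambda: {"ei": 2.0, "ie": 6.0, "ii": 6.0}
    )
    mu: float | np.ndarray = 47.0  # mV
    # external noise set so network neurons fire irregularly (ISI CV ~ 0.9
    # at 20 Hz), the asynchronous irregular state the analysis assumes
    sigma: float = 40.0            # mV * sqrt(ms)
    dt: float = 0.1                # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("population sizes must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for k in ("ei", "ie", "ii"):
            if self.fixed_bounds[k] <= 0:
                raise ValueError("fixed-block bounds must be positive")
        if self.fixed_bounds["ie"] != self.fixed_bounds["ii"]:
            raise ValueError("I->E and I->I bounds must be equal")

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    def mu_vector(self) -> np.ndarray:
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim == 0:
            return np.full(self.n, float(mu))
        if mu.shape != (self.n,):
            raise ValueError(f"mu must be scalar or length {self.n}")
        return mu.copy()


@dataclass
class WeightMatrix:
    """Plastic E->E weights; entry (i, j) is the synapse from j onto i."""

    entries: np.ndarray
    w_max: float

    def __post_init__(self) -> None:
        w = np.asarray(self.entries, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-connections are prohibited (diagonal must be 0)")
        if w.min() < 0 or w.max() > self.w_max:
            raise ValueError("weights must lie in [0, w_max]")
        self.entries = w

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def to_csv(self, path: str | Path) -> None:
        p = Path(path)
        np.savetxt(p, self.entries, delimiter=",")
        sidecar = p.with_suffix(p.suffix + ".json")
        sidecar.write_text(
            json.dumps({"orientation": "row = postsynaptic index", "w_max": self.w_max})
        )

    @classmethod
    def from_csv(cls, path: str | Path, w_max: float | None = None) -> "WeightMatrix":
        p = Path(path)
        entries = np.loadtxt(p, delimiter=",")
        if w_max is None:
            sidecar = p.with_suffix(p.suffix + ".json")
            if sidecar.exists():
                w_max = json.loads(sidecar.read_text())["w_max"]
            else:
                w_max = float(entries.max())
        return cls(entries=entries, w_max=w_max)


@dataclass
class SpikeRaster:
    """Time-sorted spike events with population bookkeeping."""

    times: np.ndarray    # ms
    ids: np.ndarray
    duration: float      # ms
    n_exc: int
    n_inh: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must align")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh

    def train(self, neuron_id: int) -> np.ndarray:
        return self.times[self.ids == neuron_id]

    def mean_rate(self, population: str = "exc", t_start: float = 0.0) -> float:
        """Mean firing rate in Hz over ``[t_start, duration]``."""
        if population == "exc":
            sel = self.ids < self.n_exc
            count_n = self.n_exc
        elif population == "inh":
            sel = self.ids >= self.n_exc
            count_n = self.n_inh
        else:
            sel = np.ones_like(self.ids, dtype=bool)
            count_n = self.n
        sel &= self.times >= t_start
        span_s = (self.duration - t_start) / 1000.0
        if span_s <= 0:
            raise ValueError("empty analysis span")
        return float(sel.sum() / count_n / span_s)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.times, "neuron_id": self.ids}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, duration: float, n_exc: int, n_inh: int) -> "SpikeRaster":
        df = pd.read_csv(path)
        return cls(
            times=df["time_ms"].to_numpy(),
            ids=df["neuron_id"].to_numpy(),
            duration=duration,
            n_exc=n_exc,
            n_inh=n_inh,
        )


@dataclass
class SteadyStateRecord:
    """Sampled mean rate and weight statistics plus the convergence verdict."""

    times: np.ndarray    # ms
    rates: np.ndarray    # Hz, mean over excitatory population
    w_mean: np.ndarray   # mV
    w_var: np.ndarray    # mV^2
    converged: bool = False
    convergence_time: float = math.nan

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.rates) == len(self.w_mean) == len(self.w_var) == n):
            raise ValueError("all series must have equal length")


def initial_weights(params: NetworkParams, rng: np.random.Generator | None = None) -> WeightMatrix:
    """Uniform-random E->E matrix on ``[0, w_max_ee]`` with zero diagonal."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    w = rng.uniform(0.0, params.w_max_ee, size=(params.n_exc, params.n_exc))
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(entries=w, w_max=params.w_max_ee)


def _full_matrix(params: NetworkParams, ee: np.ndarray) -> np.ndarray:
    """Assemble the full magnitude matrix with fixed non-plastic blocks.

    The fixed blocks are a deterministic function of the network seed, so
    repeated simulations of the same configuration share them.
    """
    rng = np.random.default_rng([params.seed, 0x5F1D])
    n_e, n_i, n = params.n_exc, params.n_inh, params.n
    W = np.zeros((n, n))
    W[:n_e, :n_e] = ee
    W[n_e:, :n_e] = rng.uniform(0, params.fixed_bounds["ei"], size=(n_i, n_e))
    W[:n_e, n_e:] = rng.uniform(0, params.fixed_bounds["ie"], size=(n_e, n_i))
    W[n_e:, n_e:] = rng.uniform(0, params.fixed_bounds["ii"], size=(n_i, n_i))
    np.fill_diagonal(W, 0.0)
    return W


def simulate(
    params: NetworkParams,
    neuron: NeuronParams,
    window: STDPWindow,
    init: WeightMatrix,
    duration: float,
    plasticity: bool = True,
    sample_interval: float = 500.0,
    detect_window: float = 10_000.0,
    slope_tol: float = 0.05,
    apply_updates: bool = True,
):
    """Integrate the network for ``duration`` ms.

    Returns ``(raster, weights, record)`` — the spike raster, the final E->E
    weight matrix and the sampled steady-state statistics.  With
    ``plasticity=False`` the returned weights equal the initial ones
    bit-exactly.  With ``apply_updates=False`` plasticity is bookkept but
    the weights stay frozen, and the accumulated drift matrix is attached to
    the record as ``record.drift`` (used by the pair analysis).

    Identical parameters and seed give identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if init.n != params.n_exc:
        raise ValueError("initial weight matrix does not match n_exc")
    if init.w_max != params.w_max_ee:
        raise ValueError("initial weight bound does not match w_max_ee")
    n_steps = int(round(duration / params.dt))
    sample_every = max(1, int(round(sample_interval / params.dt)))
    W = _full_matrix(params, init.entries)
    mu = params.mu_vector()
    # spike capacity: generous rate allowance, cf. balanced-state regimes
    cap = int(params.n * duration / 1000.0 * 400.0) + 100_000
    nearest = 1 if Pairing(window.pairing) is Pairing.NEAREST_NEIGHBOR else 0
    (
        spk_t,
        spk_id,
        overflowed,
        samp_t,
        samp_rate,
        samp_wmean,
        samp_wvar,
        samp_d01,
        samp_d10,
        dacc,
    ) = run_lif_network(
        params.n_exc,
        params.n_inh,
        params.dt,
        n_steps,
        neuron.tau_m,
        neuron.v_rest,
        neuron.v_thresh,
        neuron.v_reset,
        params.tau_s,
        W,
        mu,
        params.sigma,
        1 if plasticity else 0,
        1 if apply_updates else 0,
        window.a_plus,
        window.a_minus,
        window.tau_plus,
        window.tau_minus,
        window.shift,
        window.w_max,
        nearest,
        params.seed % (2**31),
        sample_every,
        cap,
    )
    if overflowed:
        raise RuntimeError("spike record capacity exceeded; raise the allowance")
    raster = SpikeRaster(
        times=spk_t, ids=spk_id, duration=duration, n_exc=params.n_exc, n_inh=params.n_inh
    )
    ee = W[: params.n_exc, : params.n_exc].copy()
    if plasticity and apply_updates:
        weights = WeightMatrix(entries=ee, w_max=params.w_max_ee)
    else:
        weights = WeightMatrix(entries=init.entries.copy(), w_max=params.w_max_ee)
    record = SteadyStateRecord(
        times=samp_t, rates=samp_rate, w_mean=samp_wmean, w_var=samp_wvar
    )
    if len(samp_t) >= 2 and (samp_t[-1] - samp_t[0]) >= 2 * detect_window:
        conv, t_conv = detect_steady_state(record, window_s=detect_window / 1000.0, slope_tol=slope_tol)
        record.converged = conv
        record.convergence_time = t_conv
    record.drift = dacc if not apply_updates else None
    record.drift_series = (samp_d01, samp_d10) if not apply_updates else None
    return raster, weights, record


class CalibrationError(RuntimeError):
    """Raised when the requested rate is not attainable in the search range."""


def calibrate_bias(
    params: NetworkParams,
    neuron: NeuronParams,
    target_rate: float,
    tolerance: float = 1.0,
    probe_duration: float = 4_000.0,
    mu_range: tuple[float, float] = (0.0, 160.0),
    max_iter: int = 40,
    init: WeightMatrix | None = None,
) -> float:
    """Find the external bias that yields a target mean excitatory rate.

    Runs plasticity-frozen probe simulations and bisects on the bias; the
    probe seed is fixed, so the measured rate is a deterministic,
    monotonically increasing function of the bias and the result is
    reproducible.  Raises :class:`CalibrationError` if the target cannot be
    bracketed inside ``mu_range``.
    """
    if target_rate <= 0:
        raise CalibrationError("target rate must be positive")
    if init is None:
        init = initial_weights(params)
    window = STDPWindow(a_plus=1e-9, a_minus=1e-9, tau_plus=20, tau_minus=20)
    burn = probe_duration / 4.0

    def rate_at(mu: float) -> float:
        p = replace(params, mu=mu)
        raster, _, _ = simulate(
            p, neuron, window, init, probe_duration, plasticity=False,
            sample_interval=probe_duration,
        )
        return raster.mean_rate("exc", t_start=burn)

    lo, hi = mu_range
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo <= target_rate <= r_hi):
        raise CalibrationError(
            f"target {target_rate} Hz outside attainable range [{r_lo:.2f}, {r_hi:.2f}] Hz"
        )
    mu = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mu = 0.5 * (lo + hi)
        r = rate_at(mu)
        if abs(r - target_rate) <= tolerance:
            return mu
        if r < target_rate:
            lo = mu
        else:
            hi = mu
    return mu


def detect_steady_state(
    record: SteadyStateRecord,
    window_s: float = 10.0,
    slope_tol: float = 0.05,
) -> tuple[bool, float]:
    """First time at which rate, mean weight and weight variance are flat.

    Flat means the relative change of each series across a trailing analysis
    window stays below ``slope_tol`` (change measured by a least-squares
    slope times the window span, normalized by the window-mean level).
    The record must span at least two analysis windows.
    """
    t = np.asarray(record.times, dtype=float) / 1000.0  # s
    if len(t) < 2 or (t[-1] - t[0]) < 2 * window_s:
        raise ValueError("record must cover at least two analysis windows")
    series = [np.asarray(record.rates), np.asarray(record.w_mean), np.asarray(record.w_var)]

    def flat_at(i_end: int) -> bool:
        t_end = t[i_end]
        sel = (t >= t_end - window_s) & (t <= t_end)
        if sel.sum() < 3:
            return False
        tw = t[sel]
        for s in series:
            sw = s[sel]
            level = np.abs(sw).mean()
            if level == 0:
                continue
            slope = np.polyfit(tw, sw, 1)[0]
            if abs(slope) * window_s / level > slope_tol:
                return False
        return True

    for i in range(len(t)):
        if t[i] - t[0] >= window_s and flat_at(i):
            return True, float(t[i] * 1000.0)
    return False, math.nan
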