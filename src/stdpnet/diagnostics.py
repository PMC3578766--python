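"""Asynchronous-irregular regime checks: cross-covariance and ISI CV.

The pairwise drift analysis assumes the network fires irregularly (ISI
coefficient of variation near 1) and asynchronously (average pairwise
cross-covariance near zero).  These statistics verify that assumption on a
simulated raster.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy import signal

from .network import SpikeRaster

__all__ = ["CrossCovReport", "cross_covariance", "isi_cv"]


@dataclass
class CrossCovReport:
    lags: np.ndarray          # ms
    covariance: np.ndarray    # average over sampled ordered pairs, (spikes/bin)^2
    n_pairs: int
    bin_ms: float
    duration_s: float
    mean_isi_cv: float | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["lags"] = [float(x) for x in self.lags]
        d["covariance"] = [float(x) for x in self.covariance]
        return json.dumps(d)


def _binned(train: np.ndarray, duration: float, bin_ms: float) -> np.ndarray:
    n_bins = int(duration // bin_ms)
    counts, _ = np.histogram(train, bins=n_bins, range=(0.0, n_bins * bin_ms))
    return counts.astype(float)


def cross_covariance(
    raster: SpikeRaster,
    n_pairs: int = 100,
    bin_ms: float = 1.0,
    max_lag_ms: float = 100.0,
    seed: int = 0,
    population: str = "exc",
) -> CrossCovReport:
    """Average lagged cross-covariance over randomly sampled neuron pairs.

    Each train is binned at ``bin_ms``, mean-subtracted, and the biased
    lagged covariance (normalized by the number of bins) is averaged over
    ``n_pairs`` sampled ordered pairs of distinct neurons.  Deterministic
    given ``seed``.
    """
    if raster.times.size == 0:
        raise ValueError("raster is empty")
    if bin_ms <= 0:
        raise ValueError("bin size must be positive")
    ids = np.arange(raster.n_exc) if population == "exc" else np.arange(raster.n)
    if len(ids) < 2:
        raise ValueError("need at least two neurons")
    rng = np.random.default_rng(seed)
    max_possible = len(ids) * (len(ids) - 1)
    if n_pairs > max_possible:
        raise ValueError(f"cannot sample {n_pairs} ordered pairs from {len(ids)} neurons")
    lag_bins = int(round(max_lag_ms / bin_ms))
    lags = np.arange(-lag_bins, lag_bins + 1) * bin_ms
    acc = np.zeros(len(lags))
    cache: dict[int, np.ndarray] = {}

    def series(i: int) -> np.ndarray:
        if i not in cache:
            x = _binned(raster.train(ids[i]), raster.duration, bin_ms)
            cache[i] = x - x.mean()
        return cache[i]

    done = set()
    count = 0
    while count < n_pairs:
        i, j = rng.integers(0, len(ids), size=2)
        if i == j or (i, j) in done:
            continue
        done.add((i, j))
        a, b = series(int(i)), series(int(j))
        n = len(a)
        full = signal.correlate(a, b, mode="full", method="fft") / n
        mid = n - 1  # lag = index - (n-1)
        acc += full[mid - lag_bins : mid + lag_bins + 1]
        count += 1
    return CrossCovReport(
        lags=lags,
        covariance=acc / n_pairs,
        n_pairs=n_pairs,
        bin_ms=bin_ms,
        duration_s=raster.duration / 1000.0,
    )


def isi_cv(
    raster: SpikeRaster,
    n_neurons: int = 100,
    seed: int = 0,
    population: str = "exc",
    min_spikes: int = 3,
) -> float:
    """Mean inter-spike-interval coefficient of variation over sampled neurons.

    Neurons with fewer than ``min_spikes`` spikes are skipped; if none
    qualifies an error is raised.  CV = 1 for Poisson firing, 0 for a clock.
    """
    ids = np.arange(raster.n_exc) if population == "exc" else np.arange(raster.n)
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(ids)[:n_neurons]
    cvs = []
    for i in chosen:
        t = raster.train(int(i))
        if len(t) < min_spikes:
            continue
        isi = np.diff(t)
        m = isi.mean()
        if m > 0:
            cvs.append(isi.std() / m)
    if not cvs:
        raise ValueError("no sampled neuron has enough spikes for an ISI CV")
    return float(np.mean(cvs))
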