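"""The pair-based STDP window, spike pairing schemes and hard weight bounds.

The window maps a pairing interval ``dt = t_post - t_pre`` (ms, positive when
the presynaptic spike leads) to a weight change in mV::

    dw(dt) =  a_plus  * exp(-(dt - d) / tau_plus)   for dt > d
    dw(dt) = -a_minus * exp( (dt - d) / tau_minus)  for dt < d

The temporal shift ``d`` moves the potentiation/depression boundary away from
coincidence: for ``d > 0`` a presynaptic spike that precedes the postsynaptic
spike by less than ``d`` still depresses the synapse, and for ``d < 0``
post-before-pre orderings closer than ``|d|`` potentiate it.  Conventional
STDP is ``d = 0``.

Weights are confined to ``[0, w_max]`` by hard bounds: the proposed change is
applied and the result clipped, with no weight dependence of the update
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum
import json
import math
from typing import Sequence

import numpy as np

__all__ = [
    "Pairing",
    "STDPWindow",
    "PairingEvent",
    "window_value",
    "pair_spikes",
    "apply_hard_bounds",
]


class Pairing(str, Enum):
    """Which pre/post spike pairs drive plasticity."""

    ALL_TO_ALL = "all_to_all"
    NEAREST_NEIGHBOR = "nearest_neighbor"


@dataclass(frozen=True)
class STDPWindow:
    """Parameters of the pair-based STDP rule.

    Parameters
    ----------
    a_plus, a_minus
        Maximum potentiation / depression amplitudes (mV, > 0).
    tau_plus, tau_minus
        Decay time constants of the two window lobes (ms, > 0).
    shift
        Temporal shift ``d`` of the window (ms, signed; 0 = conventional).
        A nonzero shift requires nearest-neighbor pairing: with all-to-all
        interactions a shifted window is not stable.
    pairing
        Spike-pairing scheme.
    w_max
        Upper hard bound on the weight (mV, > 0); the lower bound is 0.
    """

    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float
    shift: float = 0.0
    pairing: Pairing = Pairing.ALL_TO_ALL
    w_max: float = 2.0

    def __post_init__(self) -> None:
        if not (self.a_plus > 0 and self.a_minus > 0):
            raise ValueError("amplitudes a_plus, a_minus must be positive")
        if not (self.tau_plus > 0 and self.tau_minus > 0):
            raise ValueError("time constants tau_plus, tau_minus must be positive")
        if not self.w_max > 0:
            raise ValueError("w_max must be positive")
        if not math.isfinite(self.shift):
            raise ValueError("shift must be finite")
        pairing = Pairing(self.pairing)
        object.__setattr__(self, "pairing", pairing)
        if self.shift != 0.0 and pairing is not Pairing.NEAREST_NEIGHBOR:
            raise ValueError("shifted windows (shift != 0) require nearest-neighbor pairing")

    @property
    def integral(self) -> float:
        """Area under the window, ``a_plus*tau_plus - a_minus*tau_minus`` (mV*ms)."""
        return self.a_plus * self.tau_plus - self.a_minus * self.tau_minus

    def to_json(self) -> str:
        d = asdict(self)
        d["pairing"] = self.pairing.value
        d["shift_ms"] = d.pop("shift")
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "STDPWindow":
        d = json.loads(s)
        d["shift"] = d.pop("shift_ms")
        d["pairing"] = Pairing(d["pairing"])
        return cls(**d)


@dataclass(frozen=True)
class PairingEvent:
    """A single pre/post spike pairing.

    ``dt = t_post - t_pre`` in ms; positive means the presynaptic spike led.
    """

    dt: float
    pre_index: int
    post_index: int


def window_value(dt: float, w: STDPWindow) -> float:
    """Weight change (mV) induced by a single pairing with interval ``dt``.

    The boundary case ``dt == shift`` is assigned to the potentiation branch
    (value ``+a_plus``) for determinism, except for the unshifted window at
    ``dt == 0``, which is undefined by the two exponentials and contributes
    zero; this preserves the odd symmetry of the balanced window.
    """
    if not math.isfinite(dt):
        raise ValueError("pairing interval must be finite")
    d = w.shift
    if dt > d:
        return w.a_plus * math.exp(-(dt - d) / w.tau_plus)
    if dt < d:
        return -w.a_minus * math.exp((dt - d) / w.tau_minus)
    return 0.0 if d == 0.0 else w.a_plus


def _check_sorted(times: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and (np.any(np.diff(arr) <= 0)):
        raise ValueError(f"{name} must be strictly increasing")
    return arr


def pair_spikes(
    pre_times: Sequence[float],
    post_times: Sequence[float],
    scheme: Pairing | str,
) -> list[PairingEvent]:
    """Enumerate the spike pairings that drive plasticity for one synapse.

    ``all_to_all`` returns the full Cartesian set of pre/post pairs.

    ``nearest_neighbor`` implements the reduced symmetric scheme: each
    postsynaptic spike pairs with the most recent presynaptic spike at or
    before it, and each presynaptic spike pairs with the most recent
    postsynaptic spike at or before it.  This is the scheme realisable online
    with one last-spike-time register per train.

    Both trains must be strictly increasing; an empty train yields no pairs.
    """
    scheme = Pairing(scheme)
    pre = _check_sorted(pre_times, "pre_times")
    post = _check_sorted(post_times, "post_times")
    events: list[PairingEvent] = []
    if pre.size == 0 or post.size == 0:
        return events
    if scheme is Pairing.ALL_TO_ALL:
        for i, tpre in enumerate(pre):
            for j, tpost in enumerate(post):
                events.append(PairingEvent(dt=float(tpost - tpre), pre_index=i, post_index=j))
        return events
    # nearest-neighbor: backward-looking pairing from each spike; a pair of
    # coincident spikes is found by both look-backs but counted only once
    seen: set[tuple[int, int]] = set()
    for j, tpost in enumerate(post):
        i = int(np.searchsorted(pre, tpost, side="right")) - 1
        if i >= 0 and (i, j) not in seen:
            seen.add((i, j))
            events.append(PairingEvent(dt=float(tpost - pre[i]), pre_index=i, post_index=j))
    for i, tpre in enumerate(pre):
        j = int(np.searchsorted(post, tpre, side="right")) - 1
        if j >= 0 and (i, j) not in seen:
            seen.add((i, j))
            events.append(PairingEvent(dt=float(post[j] - tpre), pre_index=i, post_index=j))
    events.sort(key=lambda e: (e.dt, e.pre_index, e.post_index))
    return events


def apply_hard_bounds(w: float, delta: float, window: STDPWindow) -> float:
    """Apply a proposed weight change under hard bounds, ``[0, w_max]``.

    The incoming weight must already lie inside the bounds; the update is
    clipped, never reflected or rescaled.
    """
    if not (0.0 <= w <= window.w_max):
        raise ValueError(f"weight {w} outside [0, {window.w_max}] on entry")
    return min(window.w_max, max(0.0, w + delta))


def accumulate_offline(
    pre_times: Sequence[float],
    post_times: Sequence[float],
    window: STDPWindow,
) -> float:
    """Total (unclipped) weight change from a pair of recorded spike trains.

    Sums ``window_value`` over :func:`pair_spikes` under the window's own
    pairing scheme.  Used as the offline reference for the online trace /
    register implementation inside the network simulator.
    """
    return float(
        sum(window_value(ev.dt, window) for ev in pair_spikes(pre_times, post_times, window.pairing))
    )
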