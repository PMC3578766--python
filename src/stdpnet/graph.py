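"""Structure statistics on the plastic weight matrix.

The weight matrix is turned into a directed graph by thresholding: entry
``A[i, j] = 1`` iff the synapse from neuron ``j`` onto neuron ``i`` is at
least ``theta`` (by default the mean off-diagonal weight, which makes the
census insensitive to the overall weight scale).  The number of closed loops
of length ``L`` is the number of closed directed walks, ``trace(A**L)``;
node repetition is allowed.  Observed counts are compared with counts in
shuffled matrices in which the off-diagonal entries are randomly permuted —
a null that preserves the weight multiset exactly while destroying all
pairwise structure — giving per-length loop ratios and the recurrence index
(total loops of length 2..9 over the shuffled total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Sequence

import numpy as np

__all__ = [
    "AdjacencyMatrix",
    "LoopReport",
    "HubReport",
    "binarize",
    "count_loops",
    "shuffle_null",
    "loop_ratio_report",
    "disconnected_pairs",
    "hub_report",
]

# Entries of A**L are bounded by n**(L-1); beyond 2**53 float64 matmul can
# drop integer precision, so we fall back to exact object-dtype arithmetic.
_FLOAT_EXACT_LIMIT = 2.0**53


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary directed adjacency with zero diagonal and the threshold used."""

    matrix: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        object.__setattr__(self, "matrix", m.astype(np.int64))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LoopReport:
    lengths: list[int]
    counts: list[int]
    shuffle_counts: list[list[int]]  # [shuffle][length]
    ratio_mean: list[float]
    ratio_std: list[float]
    recurrence_index: float
    n_shuffles: int
    seed: int
    theta: float
    undefined_lengths: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class HubReport:
    in_degree: list[int]
    out_degree: list[int]
    slope: float | None
    intercept: float | None
    theta: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _as_weights(weights) -> np.ndarray:
    w = np.asarray(getattr(weights, "entries", weights), dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    return w


def resolve_theta(weights, theta) -> float:
    """Resolve a threshold spec; ``"mean"`` is the mean off-diagonal weight."""
    w = _as_weights(weights)
    if isinstance(theta, str):
        if theta != "mean":
            raise ValueError(f"unknown threshold spec {theta!r}")
        n = w.shape[0]
        off = ~np.eye(n, dtype=bool)
        return float(w[off].mean())
    theta = float(theta)
    if theta < 0:
        raise ValueError("threshold must be non-negative")
    return theta


def binarize(weights, theta="mean") -> AdjacencyMatrix:
    """Threshold a weight matrix into a directed adjacency matrix.

    Entry is 1 iff ``weight >= theta``; the diagonal is forced to zero
    (self-connections are prohibited in the network model).
    """
    w = _as_weights(weights)
    th = resolve_theta(w, theta)
    # >= with a relative tolerance so a weight equal to the threshold up to
    # float rounding (e.g. an all-equal matrix thresholded at its own mean)
    # counts as connected
    a = ((w >= th) | np.isclose(w, th, rtol=1e-9, atol=0.0)).astype(np.int64)
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(matrix=a, theta=th)


def count_loops(adj: AdjacencyMatrix | np.ndarray, length: int) -> int:
    """Number of closed directed walks of ``length`` steps: trace(A**L).

    Node repetition is allowed, so a single 3-cycle counts 3 walks of length
    3 (one per starting node).  Computed in int64 and verified against the
    float64 exactness limit; instances that could overflow are recomputed
    with exact Python integers.
    """
    a = adj.matrix if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=np.int64)
    if length < 2:
        raise ValueError("loop length must be >= 2 (self-connections are prohibited)")
    n = a.shape[0]
    if float(n) ** (length - 1) < _FLOAT_EXACT_LIMIT:
        p = np.linalg.matrix_power(a, length)
        return int(np.trace(p))
    # exact big-integer fallback (repeated squaring keeps matmuls at O(log L))
    ao = a.astype(object)
    result = None
    base = ao
    k = length
    while k:
        if k & 1:
            result = base if result is None else result @ base
        k >>= 1
        if k:
            base = base @ base
    return int(np.trace(result))


def shuffle_null(weights, n_shuffles: int, seed: int) -> list[np.ndarray]:
    """Shuffled versions of a weight matrix (null model).

    Each shuffle uniformly permutes the off-diagonal entries; the diagonal
    stays zero and the weight multiset is preserved exactly.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    w = _as_weights(weights)
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = w[off]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        s = np.zeros_like(w)
        s[off] = rng.permutation(vals)
        out.append(s)
    return out


def loop_ratio_report(
    weights,
    theta="mean",
    lengths: Sequence[int] = tuple(range(2, 10)),
    n_shuffles: int = 10,
    seed: int = 0,
) -> LoopReport:
    """Loop census of a weight matrix against its shuffle null.

    For each length the ratio is the observed count divided by the mean
    shuffled count; the recurrence index aggregates lengths 2..9 (all loops
    shorter than 10).  Lengths whose mean shuffled count is zero are flagged
    as undefined rather than reported as ratios.
    """
    w = _as_weights(weights)
    th = resolve_theta(w, theta)
    lengths = [int(L) for L in lengths]
    adj = binarize(w, th)
    counts = [count_loops(adj, L) for L in lengths]
    shuffles = shuffle_null(w, n_shuffles, seed)
    shuffle_counts = []
    for s in shuffles:
        sa = binarize(s, th)
        shuffle_counts.append([count_loops(sa, L) for L in lengths])
    sc = np.asarray(shuffle_counts, dtype=float)
    mean_sc = sc.mean(axis=0)
    ratio_mean, ratio_std, undefined = [], [], []
    for k, L in enumerate(lengths):
        if mean_sc[k] == 0:
            undefined.append(L)
            ratio_mean.append(float("nan"))
            ratio_std.append(float("nan"))
        else:
            ratios = counts[k] / sc[:, k]
            # ratio of observed to per-shuffle counts; spread across shuffles
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_mean.append(float(counts[k] / mean_sc[k]))
                ratio_std.append(float(np.nanstd(np.where(sc[:, k] > 0, ratios, np.nan))))
    ri_lengths = [L for L in range(2, 10) if L in lengths]
    tot_real = sum(counts[lengths.index(L)] for L in ri_lengths)
    tot_null = sum(mean_sc[lengths.index(L)] for L in ri_lengths)
    recurrence = float(tot_real / tot_null) if tot_null > 0 else float("nan")
    return LoopReport(
        lengths=lengths,
        counts=[int(c) for c in counts],
        shuffle_counts=[[int(c) for c in row] for row in shuffle_counts],
        ratio_mean=ratio_mean,
        ratio_std=ratio_std,
        recurrence_index=recurrence,
        n_shuffles=n_shuffles,
        seed=seed,
        theta=th,
        undefined_lengths=undefined,
    )


def disconnected_pairs(weights, theta="mean") -> int:
    """Unordered pairs {i, j} with both directed weights below threshold."""
    w = _as_weights(weights)
    th = resolve_theta(w, theta)
    a = binarize(w, th).matrix
    both_off = (a == 0) & (a.T == 0)
    np.fill_diagonal(both_off, False)
    return int(both_off.sum() // 2)


def hub_report(weights, theta="mean") -> HubReport:
    """Per-neuron above-threshold in/out degrees and the in-vs-out OLS slope.

    In a regime where strengthening an incoming synapse is paid for by the
    weakening of an outgoing one, in + out stays constant per neuron and the
    slope is -1.  A zero-variance out-degree leaves the slope undefined
    (``None``).
    """
    w = _as_weights(weights)
    if w.shape[0] < 3:
        raise ValueError("hub analysis needs n >= 3")
    th = resolve_theta(w, theta)
    a = binarize(w, th).matrix
    in_deg = a.sum(axis=1)   # row i: synapses onto neuron i
    out_deg = a.sum(axis=0)  # column j: synapses from neuron j
    if np.ptp(out_deg) == 0:
        slope, intercept = None, None
    else:
        b, a0 = np.polyfit(out_deg.astype(float), in_deg.astype(float), 1)
        slope, intercept = float(b), float(a0)
    return HubReport(
        in_degree=[int(d) for d in in_deg],
        out_degree=[int(d) for d in out_deg],
        slope=slope,
        intercept=intercept,
        theta=th,
    )
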