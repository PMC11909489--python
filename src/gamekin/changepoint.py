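"""Kernel change-point detection over the movement-derivative signal.

A segment's homogeneity is scored with a Gaussian (RBF) kernel cost

    c(z_a..b) = (b - a) - (1 / (b - a)) * sum_{i,j in [a,b)} exp(-gamma (z_i - z_j)^2)

which is zero for constant segments and nonnegative in general.  The
segmentation criterion V(tau) is the sum of this cost over the K+1
segments induced by breakpoints tau.  Two solvers are provided:

* ``segment_fixed_k`` — exact minimization of V for a *known* number of
  changes K, by dynamic programming over all admissible breakpoints;
* ``segment_penalized`` — penalized formulation (cost + penalty per
  change) solved with PELT pruning, for when K is unknown.

Breakpoints follow the half-open convention: a breakpoint t_k is the
first index of segment k+1, so segments are [0,t_1), [t_1,t_2), ...,
[t_K, T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (ConstantSignalError, InfeasibleSegmentationError,
                     InsufficientDataError, ParameterError)
from .geometry import DerivativeSignal


@dataclass(frozen=True)
class KernelParams:
    """RBF bandwidth gamma (> 0) and minimum segment length in samples."""

    gamma: float
    min_size: int = 5

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.min_size < 2:
            raise ParameterError("min_size must be >= 2")


@dataclass
class Segmentation:
    breakpoints: list[int]        # t_1 < ... < t_K, first index of each next segment
    criterion: float              # achieved value of V
    n_samples: int

    @property
    def k(self) -> int:
        return len(self.breakpoints)

    @property
    def n_segments(self) -> int:
        return self.k + 1

    def segments(self) -> list[tuple[int, int]]:
        cuts = [0, *self.breakpoints, self.n_samples]
        return list(zip(cuts, cuts[1:]))


def _as_values(signal) -> np.ndarray:
    if isinstance(signal, DerivativeSignal):
        return np.asarray(signal.values, dtype=float)
    return np.asarray(signal, dtype=float)


def rbf_cost(subsignal, params: KernelParams) -> float:
    """Kernel cost of one contiguous slice (direct Gram evaluation)."""
    z = _as_values(subsignal)
    n = len(z)
    if n == 0:
        raise InsufficientDataError("empty segment has no cost")
    gram = np.exp(-params.gamma * (z[:, None] - z[None, :]) ** 2)
    return float(n - gram.sum() / n)


def median_bandwidth(signal, max_points: int = 1000, seed: int = 0) -> float:
    """Median heuristic: gamma = 1 / median of squared pairwise differences.

    Pairs are taken over a deterministic subsample of at most
    ``max_points`` values.  Raises for constant signals (the caller must
    then supply gamma explicitly).
    """
    z = _as_values(signal)
    if len(z) < 2:
        raise InsufficientDataError("median_bandwidth needs >= 2 samples")
    if len(z) > max_points:
        rng = np.random.default_rng(seed)
        z = z[np.sort(rng.choice(len(z), size=max_points, replace=False))]
    sq = (z[:, None] - z[None, :]) ** 2
    iu = np.triu_indices(len(z), k=1)
    med = float(np.median(sq[iu]))
    if med <= 0:
        raise ConstantSignalError("signal has zero median pairwise difference")
    return 1.0 / med


class _CostCache:
    """O(1) segment costs from 2D prefix sums of the kernel Gram matrix."""

    def __init__(self, z: np.ndarray, gamma: float) -> None:
        gram = np.exp(-gamma * (z[:, None] - z[None, :]) ** 2)
        p = np.zeros((len(z) + 1, len(z) + 1))
        np.cumsum(np.cumsum(gram, axis=0), axis=1, out=p[1:, 1:])
        self._p = p
        self._diag = np.diagonal(p).copy()

    def cost_row(self, a: int, bs: np.ndarray) -> np.ndarray:
        """Costs c(a, b) for fixed start a and an array of ends b (b > a)."""
        lengths = bs - a
        s = self._diag[bs] - 2.0 * self._p[a, bs] + self._diag[a]
        return lengths - s / lengths

    def cost_col(self, as_: np.ndarray, b: int) -> np.ndarray:
        """Costs c(a, b) for an array of starts a and fixed end b (b > a)."""
        lengths = b - as_
        s = self._diag[b] - 2.0 * self._p[as_, b] + self._diag[as_]
        return lengths - s / lengths

    def cost(self, a: int, b: int) -> float:
        return float(self.cost_row(a, np.array([b]))[0])


def segment_fixed_k(signal, k: int, params: KernelParams) -> Segmentation:
    """Exact optimal segmentation with a known number of changes K.

    Minimizes V(tau) over all placements of K breakpoints with every
    segment at least ``params.min_size`` long.  Ties are broken toward the
    lexicographically smallest breakpoint vector.
    """
    z = _as_values(signal)
    t_n, m = len(z), params.min_size
    if k < 0:
        raise ParameterError("K must be >= 0")
    if t_n < (k + 1) * m:
        raise InfeasibleSegmentationError(
            f"T={t_n} too short for {k + 1} segments of min_size={m}")
    cache = _CostCache(z, params.gamma)
    if k == 0:
        return Segmentation([], cache.cost(0, t_n), t_n)

    inf = np.inf
    # w[j][s]: min cost of partitioning z[s:] into j segments
    w = np.full((k + 2, t_n + 1), inf)
    starts_1 = np.arange(0, t_n - m + 1)
    w[1, starts_1] = cache.cost_col(starts_1, t_n)
    for j in range(2, k + 2):
        max_start = t_n - j * m
        for s in range(0, max_start + 1):
            ts = np.arange(s + m, t_n - (j - 1) * m + 1)
            w[j, s] = np.min(cache.cost_row(s, ts) + w[j - 1, ts])

    # forward reconstruction: smallest breakpoint at each level
    breakpoints: list[int] = []
    s = 0
    for j in range(k + 1, 1, -1):
        ts = np.arange(s + m, t_n - (j - 2) * m + 1)
        totals = cache.cost_row(s, ts) + w[j - 1, ts]
        s = int(ts[int(np.argmin(totals))])
        breakpoints.append(s)
    criterion = float(w[k + 1, 0])
    return Segmentation(breakpoints, criterion, t_n)


def segment_penalized(signal, penalty: float,
                      params: KernelParams) -> Segmentation:
    """Penalized kernel change-point detection with PELT pruning.

    Minimizes sum of segment costs + penalty * (number of changes).
    ``criterion`` on the result is the unpenalized sum of segment costs.
    """
    if penalty <= 0:
        raise ParameterError("penalty must be > 0")
    z = _as_values(signal)
    t_n, m = len(z), params.min_size
    if t_n < m:
        raise InsufficientDataError(f"T={t_n} shorter than min_size={m}")
    cache = _CostCache(z, params.gamma)

    f = np.full(t_n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(t_n + 1, dtype=int)
    candidates = [0]
    for t in range(m, t_n + 1):
        cand = np.array([s for s in candidates if t - s >= m])
        if len(cand) == 0:
            continue
        totals = f[cand] + cache.cost_col(cand, t) + penalty
        i = int(np.argmin(totals))
        f[t] = totals[i]
        prev[t] = cand[i]
        # PELT prune: kernel cost is subadditive under splitting
        keep = [int(s) for s, tot in zip(cand, totals) if tot - penalty <= f[t]]
        keep += [s for s in candidates if t - s < m]   # too new to score yet
        if m <= t - m + 1 <= t_n - m:
            keep.append(t - m + 1)
        candidates = keep
    if not np.isfinite(f[t_n]):
        raise InfeasibleSegmentationError("no admissible segmentation")

    breakpoints = []
    t = t_n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            breakpoints.append(s)
        t = s
    breakpoints.reverse()
    cuts = [0, *breakpoints, t_n]
    criterion = float(sum(cache.cost(a, b) for a, b in zip(cuts, cuts[1:])))
    return Segmentation(breakpoints, criterion, t_n)
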