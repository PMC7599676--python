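"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by direct enumeration or explicit
likelihood evaluation, without sharing code paths with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
from scipy import optimize

ALL_26 = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > tuple(-c for c in d)]


def glcm_counts_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric co-occurrence counts by looping over every voxel pair."""
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = levels.shape
    for p in np.argwhere(levels > 0):
        for d in ALL_26:
            q = p + d
            if np.all(q >= 0) and np.all(q < shape):
                lq = levels[tuple(q)]
                if lq > 0:
                    counts[levels[tuple(p)] - 1, lq - 1] += 1
    return counts


def glrlm_counts_brute(levels: np.ndarray, d: tuple[int, int, int]) -> dict:
    """Run counts {(level, length): n} along direction d via line scanning."""
    shape = levels.shape
    runs: dict = {}
    dv = np.asarray(d)
    for p in itertools.product(*(range(n) for n in shape)):
        prev = np.asarray(p) - dv
        if np.all(prev >= 0) and np.all(prev < shape):
            continue  # not a line start
        # read the whole line, group consecutive equal nonzero levels
        seq = []
        q = np.asarray(p)
        while np.all(q >= 0) and np.all(q < shape):
            seq.append(int(levels[tuple(q)]))
            q = q + dv
        for lv, grp in itertools.groupby(seq):
            if lv > 0:
                length = len(list(grp))
                runs[(lv, length)] = runs.get((lv, length), 0) + 1
    return runs


def glszm_zones_brute(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) per 26-connected zone, by BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.argwhere(levels > 0):
        start = tuple(start)
        if seen[start]:
            continue
        lv = levels[start]
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            size += 1
            for d in ALL_26:
                q = tuple(np.asarray(p) + d)
                if all(0 <= qi < ni for qi, ni in zip(q, shape)):
                    if not seen[q] and levels[q] == lv:
                        seen[q] = True
                        queue.append(q)
        zones.append((int(lv), size))
    return zones


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of (pos, neg) pairs correctly ordered, ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def odds_ratio_2x2(x: np.ndarray, y: np.ndarray) -> float:
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    return (a * d) / (b * c)


def cox_neg_log_partial_likelihood(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Explicit Efron-tie negative log partial likelihood, single covariate."""
    nll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        at_risk = times >= t
        d = int(tied.sum())
        s_tied_x = float(x[tied].sum())
        sum_risk = float(np.exp(beta * x[at_risk]).sum())
        sum_tied = float(np.exp(beta * x[tied]).sum())
        nll -= beta * s_tied_x
        for ell in range(d):
            nll += math.log(sum_risk - ell / d * sum_tied)
    return nll


def cox_mle_brute(times: np.ndarray, events: np.ndarray, x: np.ndarray) -> float:
    """Maximize the written-out partial likelihood over beta."""
    res = optimize.minimize_scalar(
        lambda b: cox_neg_log_partial_likelihood(b, times, events, x),
        bounds=(-20, 20),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def log_rank_brute(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """One-df log-rank by explicit observed/expected table summation."""
    from scipy import stats

    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, df=1))


def km_empirical(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function (no censoring): S(t) = P(T > t)."""
    ts = np.unique(times)
    surv = np.array([(times > t).mean() for t in ts])
    return ts, surv


def random_levels(rng: np.random.Generator, ng: int = 4, max_side: int = 5):
    """A random small labeled ROI: levels in 1..ng inside a random mask, 0 outside."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return levels
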