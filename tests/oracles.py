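"""Independent reference implementations used only to check the package.

Each oracle is coded directly from the published definition of the method,
with plain loops and no reuse of the package's internals, so agreement is
a genuine two-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# TMM, from the trimmed-mean-of-M-values definition
# ---------------------------------------------------------------------------

def _midrank(values: list[float], i: int) -> float:
    """Rank of values[i] with ties sharing their average rank."""
    below = sum(1 for v in values if v < values[i])
    equal = sum(1 for v in values if v == values[i])
    return below + (equal + 1) / 2.0


def tmm_oracle(counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """TMM factors, geometric mean 1, coded from first principles."""
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    nz = counts[counts.sum(axis=1) > 0]
    q75 = [float(np.quantile(nz[:, j] / lib[j], 0.75)) for j in range(counts.shape[1])]
    target = sum(q75) / len(q75)
    ref = min(range(len(q75)), key=lambda j: (abs(q75[j] - target), j))

    factors = []
    for j in range(counts.shape[1]):
        ms, as_, ws = [], [], []
        for g in range(nz.shape[0]):
            o, r = nz[g, j], nz[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                as_.append((math.log2(po) + math.log2(pr)) / 2.0)
                ws.append(1.0 / ((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            rm = _midrank(ms, i)
            ra = _midrank(as_, i)
            if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
                num += ws[i] * ms[i]
                den += ws[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    log_f = [math.log(f) for f in factors]
    gm = math.exp(sum(log_f) / len(log_f))
    return np.array([f / gm for f in factors])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg, from the step-up definition
# ---------------------------------------------------------------------------

def bh_oracle(p: list[float]) -> list[float]:
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)), 1.0)
    return q


# ---------------------------------------------------------------------------
# Pearson chi-square on a 2x2 table, from the margin formulas
# ---------------------------------------------------------------------------

def chi2_2x2_oracle(table: np.ndarray) -> float:
    t = np.asarray(table, float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat


# ---------------------------------------------------------------------------
# Hypergeometric upper tail, exact integer enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_exact(k_obs: int, n_universe: int, k_universe: int, n_draw: int) -> float:
    """P(X >= k_obs), exact ratio of big-integer sums."""
    hi = min(k_universe, n_draw)
    if k_obs <= 0:
        return 1.0
    num = sum(math.comb(k_universe, i) * math.comb(n_universe - k_universe, n_draw - i)
              for i in range(k_obs, hi + 1))
    return num / math.comb(n_universe, n_draw)


# ---------------------------------------------------------------------------
# NB / Poisson two-group LRT by direct likelihood maximization
# ---------------------------------------------------------------------------

def _nb_ll(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def _fit_one(y: np.ndarray, eff: np.ndarray, phi: float) -> float:
    """Max log-likelihood of a single shared abundance (1-D optimization)."""
    if y.sum() == 0:
        return 0.0
    res = minimize_scalar(lambda b: -_nb_ll(y, np.exp(b) * eff, phi),
                          bounds=(-40.0, 15.0), method="bounded",
                          options={"xatol": 1e-13})
    return -res.fun


def nb_lrt_oracle(y1: np.ndarray, y2: np.ndarray, eff1: np.ndarray,
                  eff2: np.ndarray, phi: float) -> float:
    """LR statistic for equal abundance in two groups."""
    ll_full = _fit_one(y1, eff1, phi) + _fit_one(y2, eff2, phi)
    ll_red = _fit_one(np.concatenate([y1, y2]), np.concatenate([eff1, eff2]), phi)
    return max(2.0 * (ll_full - ll_red), 0.0)


def poisson_lrt_oracle(y1: np.ndarray, y2: np.ndarray,
                       eff1: np.ndarray, eff2: np.ndarray) -> float:
    """Closed-form Poisson deviance LRT for two groups with offsets."""
    def ll(y, eff):
        tot = y.sum()
        if tot == 0:
            return 0.0
        a = tot / eff.sum()
        mu = a * eff
        return float(np.sum(y * np.log(mu) - mu))
    full = ll(y1, eff1) + ll(y2, eff2)
    red = ll(np.concatenate([y1, y2]), np.concatenate([eff1, eff2]))
    return 2.0 * (full - red)


# ---------------------------------------------------------------------------
# Exhaustive 2-partition K-means objective
# ---------------------------------------------------------------------------

def best_two_partition_ss(x: np.ndarray) -> float:
    """Minimum total within-cluster SS over all non-trivial 2-partitions."""
    n = x.shape[0]
    best = math.inf
    for mask in itertools.product([0, 1], repeat=n - 1):
        labels = np.array([0, *mask])
        ss = 0.0
        for c in (0, 1):
            pts = x[labels == c]
            if len(pts) == 0:
                ss = math.inf
                break
            ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, ss)
    return best


# ---------------------------------------------------------------------------
# Cox-Reid common-dispersion objective via dense grid scan
# ---------------------------------------------------------------------------

def dispersion_grid_scan(objective, log10_lo: float, log10_hi: float,
                         n_points: int = 1000) -> tuple[float, float]:
    """Best phi over a dense log10 grid; returns (phi, grid step)."""
    grid = np.linspace(log10_lo, log10_hi, n_points)
    vals = [objective(g) for g in grid]
    return 10.0 ** grid[int(np.argmax(vals))], grid[1] - grid[0]
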