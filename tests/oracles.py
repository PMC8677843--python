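"""Independent brute-force oracles for the spatial statistics.

Deliberately naive (explicit loops, direct formulas) so they share no code
path with the package implementations they validate.
"""

from __future__ import annotations

import math

import numpy as np


def gi_star_brute(values, ids, neighbors) -> np.ndarray:
    """Direct evaluation of the Gi* z-score formula (binary weights, self in)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar**2)
    index = {u: i for i, u in enumerate(ids)}
    out = np.empty(n)
    for i, u in enumerate(ids):
        wsum = 0.0
        wx = 0.0
        wsq = 0.0
        for v in neighbors[u]:
            wsum += 1.0
            wsq += 1.0
            wx += x[index[v]]
        denom = s * math.sqrt((n * wsq - wsum**2) / (n - 1))
        out[i] = (wx - xbar * wsum) / denom if denom > 0 else 0.0
    return out


def moran_global_brute(values, ids, neighbors) -> float:
    """Global Moran's I with binary symmetric weights."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    index = {u: i for i, u in enumerate(ids)}
    num = 0.0
    wtot = 0.0
    for i, u in enumerate(ids):
        for v in neighbors[u]:
            j = index[v]
            if j == i:
                continue
            num += z[i] * z[j]
            wtot += 1.0
    return (n / wtot) * num / (z @ z)


def bivariate_lmi_brute(x, y, ids, neighbors) -> np.ndarray:
    """I_i = z_x,i * mean over neighbors of z_y,j (row-standardized, no self)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    index = {u: i for i, u in enumerate(ids)}
    out = np.empty(len(x))
    for i, u in enumerate(ids):
        nbrs = [v for v in neighbors[u] if index[v] != i]
        if not nbrs:
            out[i] = 0.0
            continue
        lag = sum(zy[index[v]] for v in nbrs) / len(nbrs)
        out[i] = zx[i] * lag
    return out


def q_brute(values, labels) -> float:
    """q = 1 - SSW/SST by explicit per-stratum loops."""
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    sst = sum((a - v.mean()) ** 2 for a in v)
    ssw = 0.0
    for lab in set(labels.tolist()):
        grp = v[labels == lab]
        ssw += sum((a - grp.mean()) ** 2 for a in grp)
    return 1.0 - ssw / sst


def breakdown_fixed_brute(predict, data, obs, order) -> tuple[float, list[float]]:
    """Fixed-order break-down deltas by explicit row-substitution loops."""
    ref = data.copy()
    intercept = float(np.mean(predict(ref)))
    deltas = []
    prev = intercept
    work = data.copy()
    for f in order:
        work[f] = obs[f]
        e = float(np.mean(predict(work)))
        deltas.append(e - prev)
        prev = e
    return intercept, deltas


def greedy_order_brute(predict, data, obs, features) -> list[str]:
    """Greedy break-down order recovered by exhaustive stepwise enumeration.

    At each position, every remaining feature's |change in expected
    prediction| is evaluated directly; the maximizer (lexicographic on ties)
    is appended.  Permutation enumeration collapses to this stepwise rule,
    but each expectation is computed from scratch here.
    """
    chosen: list[str] = []
    remaining = sorted(features)
    work_fixed: dict[str, float] = {}
    while remaining:
        best = None
        for f in remaining:
            trial = data.copy()
            for g, val in {**work_fixed, f: obs[f]}.items():
                trial[g] = val
            e_new = float(np.mean(predict(trial)))
            base = data.copy()
            for g, val in work_fixed.items():
                base[g] = val
            e_old = float(np.mean(predict(base)))
            key = (-abs(e_new - e_old), f)
            if best is None or key < best[0]:
                best = (key, f)
        f = best[1]
        chosen.append(f)
        work_fixed[f] = obs[f]
        remaining.remove(f)
    return chosen
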