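"""Exploratory spatial statistics: Getis-Ord Gi*, bivariate local Moran's I,
and the geodetector q-statistic.

These are the three diagnostics used to characterise the response surface
before any model is fitted: Gi* locates statistically significant clusters of
high/low mortality ("hot"/"cold" spots) and its seven-level bin
classification later serves as sampling strata for the train/validation/test
split; the bivariate local Moran's I measures the association between the
response at a unit and the spatial lag of a risk factor; the q-statistic
quantifies how much of the response variance a stratification of a risk
factor explains (stratified spatial heterogeneity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights

__all__ = [
    "HotspotResult",
    "BivariateLMIResult",
    "QStatResult",
    "gi_star",
    "classify_gi_bins",
    "bivariate_local_moran",
    "q_statistic",
    "discretize_for_q",
]

# two-sided normal cutoffs at 90 / 95 / 99% confidence
_GI_CUTOFFS = (1.645, 1.960, 2.576)


@dataclass
class HotspotResult:
    """Per-unit Gi* z-scores, two-sided p-values and seven-level bins."""

    ids: list[str]
    gi_z: np.ndarray
    p_value: np.ndarray
    gi_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gi_z": self.gi_z, "p_value": self.p_value, "gi_bin": self.gi_bin},
            index=pd.Index(self.ids, name="unit_id"),
        )


@dataclass
class BivariateLMIResult:
    """Per-unit bivariate local Moran statistics with permutation inference."""

    ids: list[str]
    I: np.ndarray
    perm_p: np.ndarray
    cluster: list[str]  # HH / HL / LH / LL / ns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"I": self.I, "perm_p": self.perm_p, "cluster": self.cluster},
            index=pd.Index(self.ids, name="unit_id"),
        )


@dataclass
class QStatResult:
    """Geodetector factor-detector output for one stratification."""

    q: float
    f_stat: float
    p_value: float
    strata_count: int
    strata_sizes: list[int]


def gi_star(values, w: SpatialWeights) -> HotspotResult:
    """Getis-Ord Gi* statistic for every unit.

    For unit i with weights w_ij (self included, the "star" form),

        z_i = [sum_j w_ij x_j - Xbar * sum_j w_ij]
              / ( S * sqrt( (n * sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1) ) )

    with Xbar the global mean and S the population standard deviation.
    A constant field has no clustering information: all z set to 0 with a
    warning.
    """
    if not w.include_self:
        raise ValueError("Gi* requires weights with include_self=True")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n != w.n:
        raise ValueError(f"values length {n} != number of units {w.n}")
    if n < 3:
        raise ValueError("Gi* needs at least 3 units")

    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    W = w.sparse()
    wx = W @ x
    wsum = np.asarray(W.sum(axis=1)).ravel()
    wsq = np.asarray(W.multiply(W).sum(axis=1)).ravel()

    if s == 0:
        warnings.warn("zero-variance field: all Gi* z-scores set to 0", stacklevel=2)
        z = np.zeros(n)
    else:
        denom = s * np.sqrt((n * wsq - wsum**2) / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(denom > 0, (wx - xbar * wsum) / denom, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return HotspotResult(list(w.ids), z, p, classify_gi_bins(z))


def classify_gi_bins(z_values) -> np.ndarray:
    """Seven-level hotspot classification of Gi* z-scores.

    |z| >= 2.576 -> +-3 (99%), >= 1.960 -> +-2 (95%), >= 1.645 -> +-1 (90%),
    else 0.  The signed bins are the strata used for the stratified split.
    """
    z = np.asarray(z_values, dtype=float)
    mag = np.select(
        [np.abs(z) >= _GI_CUTOFFS[2], np.abs(z) >= _GI_CUTOFFS[1], np.abs(z) >= _GI_CUTOFFS[0]],
        [3, 2, 1],
        default=0,
    )
    return (np.sign(z) * mag).astype(int)


def bivariate_local_moran(
    x,
    y,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> BivariateLMIResult:
    """Bivariate local Moran's I with conditional permutation inference.

    I_i = z_x,i * sum_j w_ij z_y,j on z-scored variables with row-standardized
    weights excluding self.  The permutation p-value holds unit i fixed and
    permutes the y values of the other n-1 units among i's neighbors:
    p = (#{|I_perm| >= |I_obs|} + 1) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm+1).  Cluster labels (HH/HL/LH/LL) come from the
    signs of z_x,i and the y-lag, reported only when p <= alpha.
    """
    if w.standardization != "row":
        raise ValueError("local Moran requires row-standardized weights")
    if w.include_self:
        raise ValueError("local Moran weights must not include self")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n != w.n:
        raise ValueError("x, y, and weights must have the same length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")

    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    W = w.sparse()
    lag = W @ zy
    I_obs = zx * lag

    rng = np.random.default_rng(seed)
    perm_p = np.ones(n)
    idx_all = np.arange(n)
    card = np.array([len(w.neighbors[u]) for u in w.ids])
    max_k = int(card.max()) if n else 0
    # shared conditional-permutation design: each permutation row is a random
    # ordering of the n-1 "other" units; unit i reads its first k_i entries
    perms = np.empty((n_perm, max(max_k, 1)), dtype=np.intp)
    for r in range(n_perm):
        perms[r] = rng.permutation(n - 1)[: max(max_k, 1)]
    for i in range(n):
        k = card[i]
        if k == 0:
            perm_p[i] = 1.0
            continue
        others = zy[idx_all != i]
        row = W.getrow(i)
        wvals = row.data  # neighbor weights (equal after row standardization)
        lag_perm = others[perms[:, :k]] @ wvals
        I_perm = zx[i] * lag_perm
        perm_p[i] = (np.count_nonzero(np.abs(I_perm) >= abs(I_obs[i])) + 1) / (
            n_perm + 1
        )

    cluster = []
    for i in range(n):
        if perm_p[i] > alpha or card[i] == 0:
            cluster.append("ns")
        else:
            cluster.append(("H" if zx[i] > 0 else "L") + ("H" if lag[i] > 0 else "L"))
    return BivariateLMIResult(list(w.ids), I_obs, perm_p, cluster)


def q_statistic(values, strata_labels) -> QStatResult:
    """Geodetector q-statistic (factor detector) with noncentral-F test.

    q = 1 - SSW/SST measures how much of the variance of ``values`` the
    stratification explains: 0 when strata are uninformative, 1 when values
    are constant within each stratum.  Significance follows the geodetector
    test: F = ((N-L)/(L-1)) * q/(1-q) against a noncentral F(L-1, N-L)
    with noncentrality

        lambda = (1/sigma^2) * [sum_h Nh*mean_h^2 - (sum_h sqrt(Nh)*mean_h)^2 / N]

    evaluated on the mean-centered variable: with raw strata means the
    formula is location-variant (adding a constant to every value inflates
    lambda without limit and drives p to 1), while q and F are location
    invariant; centering restores that invariance and reduces lambda to
    (approximately) the between-strata sum of squares over sigma^2.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(strata_labels)
    if len(v) != len(labels):
        raise ValueError("values and strata labels must have the same length")
    if len(v) < 2:
        raise ValueError("q-statistic needs at least 2 observations")

    uniq = pd.unique(labels)
    sizes = []
    ssw = 0.0
    means = []
    for lab in uniq:
        grp = v[labels == lab]
        if len(grp) == 0:
            raise ValueError(f"empty stratum {lab!r}")
        sizes.append(len(grp))
        means.append(grp.mean())
        ssw += ((grp - grp.mean()) ** 2).sum()
    N = len(v)
    L = len(uniq)
    sst = ((v - v.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("q-statistic undefined for constant values (SST = 0)")
    q = 1.0 - ssw / sst

    if L == 1:
        return QStatResult(q=0.0, f_stat=0.0, p_value=1.0, strata_count=1, strata_sizes=sizes)

    sizes_arr = np.asarray(sizes, dtype=float)
    means_arr = np.asarray(means, dtype=float) - v.mean()  # centered (see docstring)
    sigma_sq = sst / N  # population variance
    lam = (
        (sizes_arr * means_arr**2).sum()
        - (np.sqrt(sizes_arr) * means_arr).sum() ** 2 / N
    ) / sigma_sq
    lam = max(lam, 0.0)
    if q >= 1.0:
        f_stat = np.inf
        p_value = 0.0
    else:
        f_stat = (N - L) / (L - 1) * q / (1.0 - q)
        p_value = float(stats.ncf.sf(f_stat, L - 1, N - L, lam))
    return QStatResult(
        q=float(q),
        f_stat=float(f_stat),
        p_value=p_value,
        strata_count=L,
        strata_sizes=[int(s) for s in sizes],
    )


def discretize_for_q(values, k_strata: int = 5, method: str = "quantile") -> np.ndarray:
    """Stratify a continuous factor before the q-statistic.

    Quantile stratification gives near-equal stratum sizes (within 1 for
    distinct values); boundary ties resolve to the lower stratum
    (right-closed intervals).  Equal-interval splits the observed range into
    k equal-width bins.
    """
    v = np.asarray(values, dtype=float)
    if k_strata < 2:
        raise ValueError("k_strata must be >= 2")
    distinct = np.unique(v)
    if len(distinct) < k_strata:
        raise ValueError(
            f"only {len(distinct)} distinct values for {k_strata} strata"
        )
    if method == "quantile":
        labels = pd.qcut(v, q=k_strata, labels=False, duplicates="drop")
        if pd.isna(labels).any():
            raise ValueError("quantile discretization produced unassigned values")
        return labels.astype(int)
    if method == "equal_interval":
        edges = np.linspace(v.min(), v.max(), k_strata + 1)[1:-1]
        return np.searchsorted(edges, v, side="left").astype(int)
    raise ValueError(f"unknown discretization method {method!r}")
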