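"""Cluster-based permutation inference and group statistics across sites.

Time-resolved comparisons face a multiple-comparisons problem: a trace of
pointwise tests at alpha = 0.05 yields spurious hits.  The cluster-based
permutation test controls the family-wise error nonparametrically: compute
the pointwise statistic (t or r), mark points with two-sided p < 0.05,
group marked points into contiguous clusters (4-connected regions in 2D),
summarise each cluster (mass = summed |statistic| by default; extent =
number of points via ``size="extent"``), and compare observed cluster
sizes against the distribution of the *maximal* cluster size under random
permutation of the exchangeable labels.  A cluster is significant when its
size exceeds the 95th percentile of that null.

Three null constructions are provided, matching the exchangeability
structure of each question:

1. condition labels permuted within site (condition comparisons);
2. CP values (or traces) permuted across sites (median splits and
   across-site correlation fields);
3. choice labels permuted across trials (CP significance — lives in
   :mod:`spikecorr.choice`).

Correlation-group statistics (t-tests, ANOVA, sign test, rank correlation)
operate on Fisher-z transformed values and delegate to scipy; the partial
correlation is the Pearson correlation of the residuals of x and y after
regressing each on the control covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "Cluster", "ClusterTestResult",
    "cluster_test_conditions", "cluster_test_group_labels",
    "cluster_test_median_split",
    "cluster_test_correlation_field", "group_stats", "partial_correlation",
]

POINTWISE_ALPHA = 0.05


@dataclass
class Cluster:
    indices: np.ndarray       # flat or (n, 2) indices of member points
    mass: float               # sum of |statistic|
    extent: int
    sign: int                 # sign of the statistic inside the cluster
    p_value: float = np.nan


@dataclass
class ClusterTestResult:
    statistic: np.ndarray     # observed t or r per point (1D or 2D)
    pointwise_p: np.ndarray
    clusters: list[Cluster]
    null_max: np.ndarray      # max cluster size per permutation
    n_perm: int
    seed: int
    size: str = "mass"

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]


def _find_clusters(stat: np.ndarray, p: np.ndarray, size: str,
                   alpha: float = POINTWISE_ALPHA) -> list[Cluster]:
    mask = (p < alpha) & np.isfinite(stat)
    if stat.ndim == 1:
        structure = np.ones(3, dtype=int)
    else:
        structure = ndimage.generate_binary_structure(2, 1)   # 4-connectivity
    out: list[Cluster] = []
    for sgn in (+1, -1):
        labels, n = ndimage.label(mask & (np.sign(stat) == sgn), structure=structure)
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            vals = stat[labels == lab]
            out.append(Cluster(indices=idx.squeeze(), mass=float(np.abs(vals).sum()),
                               extent=int(vals.size), sign=sgn))
    return out


def _cluster_size(stat: np.ndarray, p: np.ndarray, size: str) -> float:
    """Maximal cluster size in one (permuted) statistic map."""
    cl = _find_clusters(stat, p, size)
    if not cl:
        return 0.0
    return max((c.mass if size == "mass" else c.extent) for c in cl)


def _attach_p(clusters: list[Cluster], null_max: np.ndarray, size: str,
              n_perm: int) -> None:
    for c in clusters:
        s = c.mass if size == "mass" else c.extent
        c.p_value = (1.0 + np.count_nonzero(null_max >= s)) / (n_perm + 1.0)


def _tstat_ind(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample t and two-sided p down axis 0."""
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(sp * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def cluster_test_conditions(trace_a: np.ndarray, trace_b: np.ndarray,
                            n_perm: int = 10000, seed: int = 0,
                            size: str = "mass") -> ClusterTestResult:
    """Compare two conditions' traces across sites, permuting condition labels.

    ``trace_a``/``trace_b`` are (n_sites, n_time) — the same sites in the
    same order, e.g. Fisher-z rSC time-courses for the ambiguous cylinder
    vs random motion.  The pointwise statistic is a two-sample t; the null
    swaps the two condition traces within a random subset of sites on each
    permutation.  Always feed unsmoothed traces.
    """
    A = np.asarray(trace_a, float)
    B = np.asarray(trace_b, float)
    if A.shape != B.shape:
        raise ValueError("condition traces must share shape (same sites, same grid)")
    if A.shape[0] < 2:
        raise ValueError("need >= 2 sites")
    if A.shape[1] == 0:
        raise ValueError("zero-length traces")
    t_obs, p_obs = _tstat_ind(A, B)
    clusters = _find_clusters(t_obs, p_obs, size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        flip = rng.random(A.shape[0]) < 0.5
        Ap = np.where(flip[:, None], B, A)
        Bp = np.where(flip[:, None], A, B)
        t, p = _tstat_ind(Ap, Bp)
        null[i] = _cluster_size(t, p, size)
    _attach_p(clusters, null, size, n_perm)
    return ClusterTestResult(statistic=t_obs, pointwise_p=p_obs, clusters=clusters,
                             null_max=null, n_perm=n_perm, seed=seed, size=size)


def cluster_test_group_labels(traces_a: np.ndarray, traces_b: np.ndarray,
                              n_perm: int = 10000, seed: int = 0,
                              size: str = "mass") -> ClusterTestResult:
    """Two independent groups of sites; the null permutes group membership.

    Unlike :func:`cluster_test_conditions`, the two groups need not be the
    same sites (e.g. rising- vs decaying-derivative subpopulations), so
    group sizes may differ and the permutation reshuffles which site falls
    in which group.
    """
    A = np.asarray(traces_a, float)
    B = np.asarray(traces_b, float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 sites per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the time grid")
    t_obs, p_obs = _tstat_ind(A, B)
    clusters = _find_clusters(t_obs, p_obs, size)
    allt = np.vstack([A, B])
    na = A.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(allt.shape[0])
        t, p = _tstat_ind(allt[perm[:na]], allt[perm[na:]])
        null[i] = _cluster_size(t, p, size)
    _attach_p(clusters, null, size, n_perm)
    return ClusterTestResult(statistic=t_obs, pointwise_p=p_obs, clusters=clusters,
                             null_max=null, n_perm=n_perm, seed=seed, size=size)


def cluster_test_median_split(values: np.ndarray, traces: np.ndarray,
                              n_perm: int = 10000, seed: int = 0,
                              size: str = "mass") -> ClusterTestResult:
    """Median-split comparison: sites above vs below the median of ``values``.

    ``values`` is one scalar per site (e.g. whole-trial CP), ``traces`` is
    (n_sites, n_time).  The pointwise statistic is a two-sample t between
    the high and low halves; the null permutes the site-to-value
    assignment.
    """
    values = np.asarray(values, float)
    traces = np.asarray(traces, float)
    if values.size < 4:
        raise ValueError("need >= 4 sites")

    def halves(v):
        med = np.median(v)
        return v > med, v < med

    hi, lo = halves(values)
    t_obs, p_obs = _tstat_ind(traces[hi], traces[lo])
    clusters = _find_clusters(t_obs, p_obs, size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        v = rng.permutation(values)
        h, l = halves(v)
        t, p = _tstat_ind(traces[h], traces[l])
        null[i] = _cluster_size(t, p, size)
    _attach_p(clusters, null, size, n_perm)
    return ClusterTestResult(statistic=t_obs, pointwise_p=p_obs, clusters=clusters,
                             null_max=null, n_perm=n_perm, seed=seed, size=size)


def _corr_field(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r across sites for every (column of X, column of Y) pair."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    nx = np.sqrt((Xc ** 2).sum(axis=0))
    ny = np.sqrt((Yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(nx, ny)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return r, p


def cluster_test_correlation_field(X: np.ndarray, Y: np.ndarray,
                                   n_perm: int = 10000, seed: int = 0,
                                   size: str = "mass") -> ClusterTestResult:
    """2D cluster test on the across-site correlation between two trace families.

    ``X`` (n_sites, n1) and ``Y`` (n_sites, n2) — e.g. the trial-time
    resolved rSC_tau derivative and the CP time-course.  The observed
    statistic is the (n1, n2) field of Pearson correlations across sites;
    the null shuffles which site's Y goes with which X.  Clusters are
    4-connected regions of two-sided pointwise p < 0.05.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of sites")
    if X.shape[0] < 4:
        raise ValueError("need >= 4 sites")
    if np.any(X.std(axis=0) == 0) or np.any(Y.std(axis=0) == 0):
        raise ValueError("a column is constant across sites; correlation undefined")
    r_obs, p_obs = _corr_field(X, Y)
    clusters = _find_clusters(r_obs, p_obs, size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(X.shape[0])
        r, p = _corr_field(X, Y[perm])
        null[i] = _cluster_size(r, p, size)
    _attach_p(clusters, null, size, n_perm)
    return ClusterTestResult(statistic=r_obs, pointwise_p=p_obs, clusters=clusters,
                             null_max=null, n_perm=n_perm, seed=seed, size=size)


# ---------------------------------------------------------------------------
# Group statistics on Fisher-z values
# ---------------------------------------------------------------------------

def group_stats(a, b=None, *, design: str = "ttest_ind") -> dict:
    """Named group test on (Fisher-z) values.

    design: ``ttest_ind`` | ``ttest_paired`` | ``ttest_1samp`` (b = popmean,
    default 0) | ``anova`` (a = list of groups) | ``sign_test`` (a = paired
    differences or a, b paired samples) | ``spearman`` (a, b paired,
    tie-corrected).
    Returns {"statistic", "p_value", "n", ...}.
    """
    if design == "anova":
        groups = [np.asarray(g, float) for g in a]
        if any(g.size < 2 for g in groups) or len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 groups of >= 2 values")
        f, p = sps.f_oneway(*groups)
        return {"statistic": float(f), "p_value": float(p),
                "n": int(sum(g.size for g in groups))}
    a = np.asarray(a, float)
    if design == "ttest_1samp":
        popmean = 0.0 if b is None else float(b)
        if a.size < 2:
            raise ValueError("need n >= 2")
        t, p = sps.ttest_1samp(a, popmean)
        return {"statistic": float(t), "p_value": float(p), "n": int(a.size)}
    if design == "sign_test":
        diff = a if b is None else a - np.asarray(b, float)
        diff = diff[diff != 0]
        if diff.size < 1:
            raise ValueError("no non-zero differences")
        npos = int(np.count_nonzero(diff > 0))
        res = sps.binomtest(npos, diff.size, 0.5)
        return {"statistic": npos, "p_value": float(res.pvalue), "n": int(diff.size)}
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in each sample")
    if design == "ttest_ind":
        t, p = sps.ttest_ind(a, b)
    elif design == "ttest_paired":
        t, p = sps.ttest_rel(a, b)
    elif design == "spearman":
        t, p = sps.spearmanr(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return {"statistic": float(t), "p_value": float(p), "n": int(a.size)}


def partial_correlation(x, y, control) -> dict:
    """Linear partial correlation of x and y given one control covariate.

    Residualises x and y on [1, control] by least squares and correlates
    the residuals; p-value from the t distribution with n - 3 degrees of
    freedom.  A constant control reduces to the plain correlation and is
    flagged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(control, float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 complete sites")
    if np.std(c) == 0:
        r, p = sps.pearsonr(x, y)
        return {"r": float(r), "p_value": float(p), "n": n, "degenerate_control": True}
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a residual that is numerically zero means the control explains that
    # variable fully; the partial correlation is then zero by convention
    if (np.std(rx) <= 1e-10 * max(1e-300, np.std(x))
            or np.std(ry) <= 1e-10 * max(1e-300, np.std(y))):
        return {"r": 0.0, "p_value": 1.0, "n": n, "degenerate_control": False,
                "degenerate_residual": True}
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1 - r ** 2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return {"r": r, "p_value": p, "n": n, "degenerate_control": False}
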