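"""Spike-count (noise) correlations: detrended rSC, time-courses, and lagged matrices.

The central quantity is rSC, the Pearson correlation between the SU's and
MU's trial-by-trial responses to repeats of one stimulus condition.  Raw
counts are contaminated by slow drifts in excitability, so each trial's
response is first converted to a z-score against the local mean and SD of
its up-to-10 neighbouring trials (5 before, 5 after, current trial
excluded)::

    z_i(k) = (r_i(k) - mu_i) / sigma_i

At sequence edges the window truncates to the available neighbours; when
the neighbourhood SD is zero the z-score is defined as 0, so constant
stretches contribute no correlation but keep the trial count fixed.
Before any of this, outlier trials (count more than 3 SD from the unit's
mean over all trials, either unit) are removed once per condition, and the
same retained-trial set is reused by every time-resolved analysis.

Group statistics on rSC always run on the Fisher-z (atanh) scale.

Time-resolved variants:

* a sliding-window time-course (100 ms window, 1 ms steps by default) with
  the same detrending applied within each window;
* the lagged rSC matrix over 20 non-overlapping 100 ms bins — entry (i, j)
  is the detrended correlation between the SU count in bin i and the MU
  count in bin j — whose diagonal is the "instantaneous" correlation
  rSC_tau=0 and whose near-diagonal average (4 leading + 4 lagging
  entries, diagonal excluded, edge-clipped) is rSC_tau=4;
* a quadratic trend fit to rSC_tau over trial time whose derivative
  indexes whether correlation at ~hundreds-of-ms lags is rising or
  decaying through the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter1d
from scipy.special import gammaln

from .session import Session

__all__ = [
    "ZScoredCounts", "CorrelationResult", "LaggedCorrelationMatrix", "TrendFit",
    "remove_outlier_trials", "zscore_sliding", "zscore_sliding_matrix",
    "compute_rsc", "rsc_timecourse", "rsc_matrix", "rsc_tau", "fit_trend",
    "smooth_for_display", "fisher_z", "fisher_z_inverse",
    "sliding_zscore_attenuation",
]

HALF_WINDOW_TRIALS = 5
OUTLIER_SD = 3.0


def sliding_zscore_attenuation(half_window: int = HALF_WINDOW_TRIALS) -> float:
    """Expected multiplicative shrinkage of Pearson r under sliding z-scoring.

    Each trial is divided by an SD estimated from its m = 2*half_window
    neighbours.  For (approximately) normal responses the neighbourhood
    variance is sigma^2 * chi2_nu / nu with nu = m - 1 and is independent
    of the current trial, so the z-scored correlation converges to

        r * (E[1/S])^2 / E[1/S^2]  =  r * (nu - 2)/2 * [Gamma((nu-1)/2) / Gamma(nu/2)]^2

    (treating the two units' SD estimates as independent; their coupling
    is O(r^2) and negligible at the correlations considered here).  For
    the default window this is ~0.931 — detrending buys drift immunity at
    the price of a ~7% downward bias, which cancels in any comparison
    between conditions analysed identically.
    """
    nu = 2 * half_window - 1
    if nu <= 2:
        raise ValueError("window too small for a finite attenuation factor")
    return (nu - 2) / 2.0 * float(np.exp(2 * (gammaln((nu - 1) / 2)
                                              - gammaln(nu / 2))))


def fisher_z(r):
    """atanh with clipping at |r| = 1 - 1e-12 so perfect correlations stay finite."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def fisher_z_inverse(z):
    return np.tanh(z)


def remove_outlier_trials(su_counts, mu_counts, sd_thresh: float = OUTLIER_SD) -> np.ndarray:
    """Indices of trials retained after the 3-SD outlier rule.

    Mean and SD are computed once over all trials (no iteration); a trial
    is removed when either unit's count deviates by more than
    ``sd_thresh`` SDs.
    """
    su = np.asarray(su_counts, float)
    mu = np.asarray(mu_counts, float)
    if su.size < 5:
        raise ValueError("need >= 5 trials")
    keep = np.ones(su.size, dtype=bool)
    for x in (su, mu):
        sd = x.std(ddof=1)
        if sd > 0:
            keep &= np.abs(x - x.mean()) <= sd_thresh * sd
    return np.flatnonzero(keep)


@dataclass
class ZScoredCounts:
    z: np.ndarray          # per-trial z-scores, recorded order preserved
    mu: np.ndarray         # local neighbourhood mean per trial
    sigma: np.ndarray      # local neighbourhood SD per trial
    unreliable: np.ndarray  # True where < 3 neighbours were available
    half_window: int = HALF_WINDOW_TRIALS


def zscore_sliding_matrix(counts: np.ndarray,
                          half_window: int = HALF_WINDOW_TRIALS
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-trial z-score down axis 0 of a (n_trials, n_columns) matrix.

    Vectorised over columns; returns (z, mu, sigma, unreliable).  The
    neighbourhood excludes the current trial, truncates at the edges, and
    uses the sample SD (ddof=1).  sigma == 0 yields z == 0.
    """
    X = np.atleast_2d(np.asarray(counts, float))
    squeeze = X.shape[0] == 1 and np.asarray(counts).ndim == 1
    if squeeze:
        X = np.asarray(counts, float)[:, None]
    n = X.shape[0]
    kernel = np.ones(2 * half_window + 1)
    kernel[half_window] = 0.0
    ncount = correlate1d(np.ones(n), kernel, mode="constant")
    s1 = correlate1d(X, kernel, axis=0, mode="constant")
    s2 = correlate1d(X ** 2, kernel, axis=0, mode="constant")
    c = ncount[:, None]
    mu = s1 / c
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - c * mu ** 2) / (c - 1)
    var = np.clip(var, 0.0, None)
    sigma = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (X - mu) / sigma
    z[~np.isfinite(z)] = 0.0
    unreliable = ncount < 3
    if squeeze:
        return z[:, 0], mu[:, 0], sigma[:, 0], unreliable
    return z, mu, sigma, unreliable


def zscore_sliding(counts, half_window: int = HALF_WINDOW_TRIALS) -> ZScoredCounts:
    """Sliding-trial z-score of one unit's per-trial counts (recorded order)."""
    counts = np.asarray(counts, float)
    z, mu, sigma, unreliable = zscore_sliding_matrix(counts, half_window)
    return ZScoredCounts(z=z, mu=mu, sigma=sigma, unreliable=unreliable,
                         half_window=half_window)


@dataclass
class CorrelationResult:
    r_sc: float
    fisher_z: float
    n_trials: int
    window: tuple[float, float] | None  # (start_ms, end_ms); None = whole trial
    valid: bool = True


def compute_rsc(su_z: ZScoredCounts | np.ndarray, mu_z: ZScoredCounts | np.ndarray,
                window: tuple[float, float] | None = None) -> CorrelationResult:
    """Pearson correlation of the two detrended response vectors."""
    a = su_z.z if isinstance(su_z, ZScoredCounts) else np.asarray(su_z, float)
    b = mu_z.z if isinstance(mu_z, ZScoredCounts) else np.asarray(mu_z, float)
    if a.size != b.size:
        raise ValueError("trial sets differ between units")
    if a.std() == 0 or b.std() == 0:
        return CorrelationResult(r_sc=np.nan, fisher_z=np.nan, n_trials=a.size,
                                 window=window, valid=False)
    r = float(np.corrcoef(a, b)[0, 1])
    return CorrelationResult(r_sc=r, fisher_z=float(fisher_z(r)),
                             n_trials=a.size, window=window)


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, m) matrices."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac ** 2).sum(axis=0) * (Bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def sliding_window_counts(session: Session, indices, unit: str,
                          window_ms: float = 100.0, step_ms: float = 1.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(n_trials, n_windows) count matrix and window-centre times.

    Windows are [c - w/2, c + w/2) around centres stepping by ``step_ms``,
    clipped to the trial; computed from the 1 ms binary trains by
    cumulative sum, so cost is independent of step size.
    """
    T = session.trial_duration_ms
    X = session.binary_trains(unit, indices).astype(float)
    csum = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    centers = np.arange(window_ms / 2.0, T - window_ms / 2.0 + 1e-9, step_ms)
    lo = np.clip(np.round(centers - window_ms / 2.0).astype(int), 0, T)
    hi = np.clip(np.round(centers + window_ms / 2.0).astype(int), 0, T)
    counts = csum[:, hi] - csum[:, lo]
    return counts, centers


def rsc_timecourse(session: Session, indices, window_ms: float = 100.0,
                   step_ms: float = 1.0, half_window: int = HALF_WINDOW_TRIALS
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detrended rSC in a sliding time window.

    Returns (centers_ms, r, n_trials).  Statistics must use the raw trace;
    see :func:`smooth_for_display` for presentation smoothing.
    """
    su, centers = sliding_window_counts(session, indices, "SU", window_ms, step_ms)
    mu, _ = sliding_window_counts(session, indices, "MU", window_ms, step_ms)
    zs, *_ = zscore_sliding_matrix(su, half_window)
    zm, *_ = zscore_sliding_matrix(mu, half_window)
    r = _columnwise_pearson(zs, zm)
    return centers, r, np.full(centers.size, su.shape[0])


def smooth_for_display(trace: np.ndarray, sd_ms: float = 30.0,
                       step_ms: float = 1.0) -> np.ndarray:
    """Gaussian smoothing for plots only — never applied before statistics."""
    return gaussian_filter1d(np.asarray(trace, float), sd_ms / step_ms,
                             mode="nearest")


@dataclass
class LaggedCorrelationMatrix:
    matrix: np.ndarray        # (n_bins, n_bins); rows = SU bin, columns = MU bin
    bin_centers_ms: np.ndarray
    bin_ms: float
    n_trials: int

    @property
    def diagonal(self) -> np.ndarray:
        """rSC_tau=0: instantaneous (same-bin) correlation per time-bin."""
        return np.diag(self.matrix)


def rsc_matrix(session: Session, indices, bin_ms: float = 100.0,
               half_window: int = HALF_WINDOW_TRIALS) -> LaggedCorrelationMatrix:
    """rSC between every pair of non-overlapping time-bins (SU bin i vs MU bin j)."""
    T = session.trial_duration_ms
    edges = np.arange(0.0, T + 1e-9, bin_ms)
    idx = np.asarray(indices, int)
    su = session.binned_counts("SU", idx, edges)
    mu = session.binned_counts("MU", idx, edges)
    zs, *_ = zscore_sliding_matrix(su, half_window)
    zm, *_ = zscore_sliding_matrix(mu, half_window)
    A = zs - zs.mean(axis=0)
    B = zm - zm.mean(axis=0)
    na = np.sqrt((A ** 2).sum(axis=0))
    nb = np.sqrt((B ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (A.T @ B) / np.outer(na, nb)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LaggedCorrelationMatrix(matrix=M, bin_centers_ms=centers,
                                   bin_ms=bin_ms, n_trials=idx.size)


def rsc_tau(lagmat: LaggedCorrelationMatrix, tau: int = 4) -> np.ndarray:
    """Near-diagonal lagged correlation per time-bin.

    For bin i, averages the entries at offsets 1..tau along both the row
    (SU bin i vs earlier/later MU bins) and the column (earlier/later SU
    bins vs MU bin i), excluding the diagonal and clipping at the matrix
    edges.  tau=0 returns the diagonal.
    """
    M = lagmat.matrix
    n = M.shape[0]
    if tau == 0:
        return np.diag(M).copy()
    out = np.empty(n)
    for i in range(n):
        vals = []
        for k in range(1, tau + 1):
            if i + k < n:
                vals.extend([M[i, i + k], M[i + k, i]])
            if i - k >= 0:
                vals.extend([M[i, i - k], M[i - k, i]])
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        out[i] = v.mean() if v.size else np.nan
    return out


@dataclass
class TrendFit:
    coefficients: np.ndarray   # quadratic coefficients, highest power first (per ms)
    derivative: np.ndarray     # d(rSC_tau)/dt at each evaluation time
    times_ms: np.ndarray
    mean_derivative: float     # derivative at the trial midpoint


def fit_trend(values: np.ndarray, times_ms: np.ndarray,
              eval_times_ms: np.ndarray | None = None) -> TrendFit:
    """Least-squares quadratic over trial time and its exact derivative.

    The derivative of the fitted parabola, 2*a*t + b, is a linear
    trial-time-resolved index of whether the lagged correlation is rising
    (positive) or decaying (negative); the scalar summary is its value at
    the trial midpoint.
    """
    values = np.asarray(values, float)
    times_ms = np.asarray(times_ms, float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        raise ValueError("need >= 3 finite points for a quadratic trend")
    coeffs = np.polyfit(times_ms[ok], values[ok], deg=2)
    if eval_times_ms is None:
        eval_times_ms = times_ms
    deriv = 2.0 * coeffs[0] * eval_times_ms + coeffs[1]
    midpoint = (times_ms[ok].min() + times_ms[ok].max()) / 2.0
    return TrendFit(coefficients=coeffs, derivative=deriv, times_ms=eval_times_ms,
                    mean_derivative=float(2.0 * coeffs[0] * midpoint + coeffs[1]))
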