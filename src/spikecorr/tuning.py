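"""Tuning-curve fits, the F-index selectivity measure, and SU/MU pair classification.

All fitting and the ANOVA behind the F-index operate on square-root
transformed firing rates (spikes/s per stimulus presentation), which
removes the approximately linear variance-to-mean relationship of spike
counts and makes the homoscedasticity assumption of least squares and the
ANOVA reasonable.

Direction tuning is a circular bell (von Mises shaped)::

    r(theta) = baseline + amplitude * exp(kappa * (cos(theta - theta_pref) - 1))

normalized so ``amplitude`` is the modulation depth between the preferred
direction and its antipode at large kappa.  Rotation (disparity) tuning is
a cumulative-Gaussian sigmoid::

    r(x) = baseline + amplitude * Phi((x - midpoint) / sd)

with ``amplitude``'s sign giving the preferred rotation (positive =
response grows toward counter-clockwise, i.e. positive disparity).

Fits minimise squared error with a derivative-free Nelder–Mead simplex,
restarted from 8 preferred-direction (or midpoint-sign) starts; a fit that
converges from no start is flagged rather than silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

__all__ = [
    "TuningFit", "PairSimilarity", "FIndexResult",
    "sqrt_transform_rates", "von_mises_curve", "cumulative_gaussian_curve",
    "fit_direction_tuning", "fit_cylinder_tuning", "f_index",
    "classify_pair", "circular_distance_deg",
]

#: a unit is "strongly" tuned when its F-index exceeds this
STRONG_F_INDEX = 0.1
#: direction preferences within this circular distance count as matching
MATCH_DIRECTION_DEG = 90.0


def sqrt_transform_rates(rates) -> np.ndarray:
    """Element-wise square root of non-negative firing rates (variance stabilisation)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("firing rates must be >= 0")
    return np.sqrt(rates)


def von_mises_curve(theta_deg, baseline, amplitude, pref_deg, kappa):
    th = np.radians(np.asarray(theta_deg, float) - pref_deg)
    return baseline + amplitude * np.exp(kappa * (np.cos(th) - 1.0))


def cumulative_gaussian_curve(x, baseline, amplitude, midpoint, sd):
    return baseline + amplitude * ndtr((np.asarray(x, float) - midpoint) / sd)


@dataclass
class TuningFit:
    kind: str                      # 'direction' | 'cylinder'
    params: dict                   # curve parameters, keys per curve family
    variance_explained: float
    converged: bool
    x: np.ndarray                  # probed directions (deg) or disparities (deg)
    raw_means: np.ndarray          # untransformed mean rates per probed value
    f_index: float | None = None   # attached by the caller when trialwise data exist
    ms_treatment: float | None = None
    ms_error: float | None = None

    @property
    def preferred(self) -> float:
        """Preferred direction in degrees, or preferred rotation sign (+1 CCW / -1 CW)."""
        if self.kind == "direction":
            return self.params["pref_deg"] % 360.0
        return 1.0 if self.params["amplitude"] >= 0 else -1.0

    def predict(self, x):
        if self.kind == "direction":
            p = self.params
            return von_mises_curve(x, p["baseline"], p["amplitude"],
                                   p["pref_deg"], p["kappa"])
        p = self.params
        return cumulative_gaussian_curve(x, p["baseline"], p["amplitude"],
                                         p["midpoint"], p["sd"])


def _fit(residual_fn, starts, bounds_check=None, maxiter=2000):
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(residual_fn, x0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-12})
        ok = res.success and (bounds_check is None or bounds_check(res.x))
        any_ok = any_ok or ok
        if best is None or res.fun < best.fun:
            best = res
    return best, any_ok


def fit_direction_tuning(directions_deg, mean_rates) -> TuningFit:
    """Fit the circular bell to mean rates at >= 6 directions spanning 360 deg.

    ``mean_rates`` are raw spikes/s; the fit itself runs on the sqrt scale.
    """
    directions_deg = np.asarray(directions_deg, float)
    mean_rates = np.asarray(mean_rates, float)
    if np.unique(directions_deg % 360.0).size < 6:
        raise ValueError("need >= 6 distinct directions")
    y = sqrt_transform_rates(mean_rates)

    def sse(p):
        b, a, pref, kappa = p
        if kappa <= 0:
            return 1e12
        r = von_mises_curve(directions_deg, b, a, pref, kappa) - y
        return float(r @ r)

    span = y.max() - y.min()
    starts = [np.array([y.min(), max(span, 1e-3), pref0, 2.0])
              for pref0 in np.arange(0, 360, 45.0)]
    best, ok = _fit(sse, starts, bounds_check=lambda p: p[3] > 0)
    b, a, pref, kappa = best.x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ve = 1.0 - best.fun / ss_tot if ss_tot > 0 else 0.0
    return TuningFit(kind="direction",
                     params={"baseline": b, "amplitude": a,
                             "pref_deg": pref % 360.0, "kappa": kappa},
                     variance_explained=ve, converged=ok,
                     x=directions_deg, raw_means=mean_rates)


def fit_cylinder_tuning(disparities_deg, mean_rates) -> TuningFit:
    """Fit the sigmoid to mean rates over a narrow disparity range around zero."""
    disparities_deg = np.asarray(disparities_deg, float)
    mean_rates = np.asarray(mean_rates, float)
    if np.unique(disparities_deg).size < 3:
        raise ValueError("need >= 3 distinct disparities")
    if not (np.any(disparities_deg > 0) and np.any(disparities_deg < 0)):
        raise ValueError("need disparities of both signs")
    y = sqrt_transform_rates(mean_rates)

    def sse(p):
        b, a, mid, sd = p
        if sd <= 0:
            return 1e12
        r = cumulative_gaussian_curve(disparities_deg, b, a, mid, sd) - y
        return float(r @ r)

    scale = np.abs(disparities_deg).max()
    span = y.max() - y.min()
    starts = []
    for sign in (+1, -1):
        for sd0 in (scale / 4, scale):
            for mid0 in (0.0, scale / 4):
                starts.append(np.array([y.min() if sign > 0 else y.max(),
                                        sign * max(span, 1e-3), mid0, sd0]))
    best, ok = _fit(sse, starts, bounds_check=lambda p: p[3] > 0)
    b, a, mid, sd = best.x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ve = 1.0 - best.fun / ss_tot if ss_tot > 0 else 0.0
    return TuningFit(kind="cylinder",
                     params={"baseline": b, "amplitude": a, "midpoint": mid, "sd": sd},
                     variance_explained=ve, converged=ok,
                     x=disparities_deg, raw_means=mean_rates)


@dataclass
class FIndexResult:
    f_index: float
    ms_treatment: float
    ms_error: float


def f_index(groups) -> FIndexResult:
    """Selectivity index MS_treatment / (MS_error + MS_treatment).

    ``groups`` is a sequence of per-condition arrays of trialwise firing
    rates (spikes/s).  The one-way-ANOVA mean squares are computed on the
    square-root transformed responses.  0 = untuned, 1 = noiseless tuning.
    """
    gs = [sqrt_transform_rates(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 condition groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs >= 2 trials")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    n = all_vals.size
    k = len(gs)
    ss_treat = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_err = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    ms_treat = ss_treat / (k - 1)
    ms_err = ss_err / (n - k)
    denom = ms_treat + ms_err
    # guard against pure floating-point residue when all responses are equal
    tiny = 1e-18 * max(1.0, float(grand) ** 2)
    f = ms_treat / denom if denom > tiny else 0.0
    return FIndexResult(f_index=float(f), ms_treatment=float(ms_treat),
                        ms_error=float(ms_err))


def circular_distance_deg(a: float, b: float) -> float:
    """Shortest angular distance between two directions, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


@dataclass
class PairSimilarity:
    r_signal: float
    matched: bool
    strong: bool


def classify_pair(su_fit: TuningFit, mu_fit: TuningFit) -> PairSimilarity:
    """Strong/matching classification of an SU/MU pair.

    strong: both F-indices above 0.1 (requires ``f_index`` attached to each
    fit).  matched: same preferred rotation sign (cylinder) or fitted
    preferred directions within 90 deg (direction).  r_signal: Pearson
    correlation of the two *raw* mean tuning vectors over the common probed
    conditions.
    """
    if su_fit.kind != mu_fit.kind:
        raise ValueError(f"cannot compare {su_fit.kind!r} with {mu_fit.kind!r} fits")
    if su_fit.f_index is None or mu_fit.f_index is None:
        raise ValueError("attach f_index to both fits before classifying")
    strong = su_fit.f_index > STRONG_F_INDEX and mu_fit.f_index > STRONG_F_INDEX
    if su_fit.kind == "direction":
        matched = circular_distance_deg(su_fit.preferred,
                                        mu_fit.preferred) < MATCH_DIRECTION_DEG
    else:
        matched = su_fit.preferred == mu_fit.preferred
    # align the raw tuning vectors on common probed values
    common, ia, ib = np.intersect1d(su_fit.x, mu_fit.x, return_indices=True)
    if common.size < 3:
        raise ValueError("fewer than 3 common probed conditions")
    a = su_fit.raw_means[ia]
    b = mu_fit.raw_means[ib]
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(a, b)[0, 1])
    return PairSimilarity(r_signal=r, matched=bool(matched), strong=bool(strong))
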