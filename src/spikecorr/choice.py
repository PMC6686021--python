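"""Choice probabilities: ROC separation of firing on preferred- vs null-choice trials.

A choice probability (CP) measures how well a unit's trial-by-trial firing
predicts the subject's perceptual report on ambiguous stimuli.  Trials are
pooled by the recorded choice; CP is the area under the ROC curve
separating the two rate distributions, computed exactly as the normalized
Mann–Whitney pair count::

    CP = ( #{(p, q): p > q} + 0.5 * #{(p, q): p == q} ) / (n_pref * n_null)

over all pairs of a preferred-choice rate p and a null-choice rate q.
CP = 0.5 means no choice information; CP > 0.5 means higher firing on
preferred-choice trials.  The preferred choice comes from the unit's
rotation tuning fit and is never refit from the choice data itself (doing
so would bias CP away from 0.5 by selection).

Significance is assessed by permuting the choice labels across trials and
counting permuted CPs at least as large as the observed one (one-sided,
with the +1 small-sample correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["CPResult", "compute_cp", "cp_timecourse", "cp_significance",
           "median_split_by_cp", "MIN_TRIALS_PER_CHOICE"]

#: minimum trials per choice group for a defined CP (configurable per call)
MIN_TRIALS_PER_CHOICE = 5


@dataclass
class CPResult:
    cp: float
    n_pref: int
    n_null: int
    window: tuple[float, float] | None = None
    p_value: float | None = None
    valid: bool = True


def _roc_area(pref: np.ndarray, null: np.ndarray) -> float:
    """Mann–Whitney U / (n_pref * n_null) via midranks (exact tie handling)."""
    combined = np.concatenate([pref, null])
    ranks = rankdata(combined)
    u = ranks[:pref.size].sum() - pref.size * (pref.size + 1) / 2.0
    return float(u / (pref.size * null.size))


def compute_cp(rates, choices, preferred_choice,
               min_per_group: int = MIN_TRIALS_PER_CHOICE,
               window: tuple[float, float] | None = None) -> CPResult:
    """ROC-area CP of one unit.

    ``choices`` is an array of labels (e.g. 'CW'/'CCW'); trials whose label
    equals ``preferred_choice`` form the preferred group.  When either
    group is below ``min_per_group`` the CP is flagged undefined rather
    than returned from a degenerate ROC.
    """
    rates = np.asarray(rates, float)
    choices = np.asarray(choices)
    pref = rates[choices == preferred_choice]
    null = rates[choices != preferred_choice]
    if pref.size < min_per_group or null.size < min_per_group:
        return CPResult(cp=np.nan, n_pref=pref.size, n_null=null.size,
                        window=window, valid=False)
    return CPResult(cp=_roc_area(pref, null), n_pref=pref.size,
                    n_null=null.size, window=window)


def cp_timecourse(counts_matrix: np.ndarray, centers_ms: np.ndarray,
                  choices, preferred_choice,
                  min_per_group: int = MIN_TRIALS_PER_CHOICE) -> np.ndarray:
    """CP per sliding-window column of a (n_trials, n_windows) count matrix.

    Returns the CP trace (NaN where undefined).  Smoothing, if any, is for
    display; statistics run on the raw trace.
    """
    choices = np.asarray(choices)
    is_pref = choices == preferred_choice
    n_p, n_n = int(is_pref.sum()), int((~is_pref).sum())
    if n_p < min_per_group or n_n < min_per_group:
        return np.full(centers_ms.size, np.nan)
    ranks = np.apply_along_axis(rankdata, 0, counts_matrix)
    u = ranks[is_pref].sum(axis=0) - n_p * (n_p + 1) / 2.0
    return u / (n_p * n_n)


def cp_significance(rates, choices, preferred_choice, n_perm: int = 10000,
                    seed: int = 0,
                    min_per_group: int = MIN_TRIALS_PER_CHOICE) -> CPResult:
    """Permutation significance of a whole-trial CP.

    Choice labels are permuted across trials ``n_perm`` times; the
    one-sided p-value is (1 + #{CP_perm >= CP_obs}) / (n_perm + 1),
    significant when the observed CP exceeds the permutation 95th
    percentile.
    """
    res = compute_cp(rates, choices, preferred_choice, min_per_group)
    if not res.valid:
        return res
    rates = np.asarray(rates, float)
    choices = np.asarray(choices)
    is_pref = choices == preferred_choice
    ranks = rankdata(rates)
    offset = res.n_pref * (res.n_pref + 1) / 2.0
    norm = res.n_pref * res.n_null
    rng = np.random.default_rng(seed)
    masks = np.tile(is_pref, (n_perm, 1))
    masks = rng.permuted(masks, axis=1)
    cp_perm = (masks @ ranks - offset) / norm
    p = (1.0 + np.count_nonzero(cp_perm >= res.cp)) / (n_perm + 1.0)
    res.p_value = float(p)
    return res


def median_split_by_cp(cp_values, curves: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split sites by the median CP and average their curves per half.

    ``curves`` is (n_sites, n_points) — e.g. rCCG curves or Fisher-z rSC
    traces; averaging happens on the given scale (transform to Fisher z
    first for correlations).  A site exactly at the median joins neither
    half.  Returns (low_idx, high_idx, low_mean, high_mean).
    """
    cp_values = np.asarray(cp_values, float)
    curves = np.asarray(curves, float)
    if cp_values.size < 4:
        raise ValueError("need >= 4 sites for a median split")
    med = np.median(cp_values)
    low = np.flatnonzero(cp_values < med)
    high = np.flatnonzero(cp_values > med)
    return low, high, curves[low].mean(axis=0), curves[high].mean(axis=0)
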