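"""End-to-end study pipeline over a cohort of SU/MU sessions.

Runs, per site: inclusion filters -> tuning fits and strong/matching
classification -> whole-trial detrended rSC per condition class (ambiguous
cylinder / unambiguous cylinder, pooled across non-zero disparities on the
Fisher-z scale / random motion) -> shift-predictor-corrected CCG and the
rCCG timescale curve -> choice probability with permutation significance
on behaviourally eligible sites -> rSC and CP time-courses, the lagged
rSC matrix, rSC_tau traces and their quadratic trend.  Population stages
then run the cluster-based permutation tests: condition differences of the
rSC time-course, the across-site correlation field linking the rSC_tau
derivative to the CP time-course, and the derivative-sign split of CP
traces.

Every number in the report is produced by the public operation of the
module that owns it; the pipeline only routes data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ccg as ccgmod
from . import choice as choicemod
from . import ratecorr, stats, tuning
from .session import (Session, apply_behavioural_filters, apply_site_filters,
                      condition_key)
from .synth import Condition, GeneratorConfig, generate_session

__all__ = ["StudyConfig", "SiteResult", "StudyReport", "run_study",
           "simulate_cohort", "default_cohort_config"]


@dataclass
class StudyConfig:
    n_perm: int = 10000
    seed: int = 0
    window_ms: float = 100.0
    step_ms: float = 50.0          # time-course sampling; 1 ms reproduces full resolution
    matrix_bin_ms: float = 100.0
    rsc_tau: int = 4
    require_strong_matching: bool = False
    min_trials_per_choice: int = choicemod.MIN_TRIALS_PER_CHOICE
    skip_onset_ms: int = 0


@dataclass
class SiteResult:
    site_id: str
    included: bool
    cp_eligible: bool | None
    rsc: dict = field(default_factory=dict)          # class -> CorrelationResult
    rccg: dict = field(default_factory=dict)         # class -> TimescaleCurve
    cp: choicemod.CPResult | None = None
    strong: bool | None = None
    matched: bool | None = None
    r_signal: float | None = None
    f_cylinder_su: float | None = None
    rsc_trace: dict = field(default_factory=dict)    # class -> (centers, fisher-z trace)
    cp_trace: np.ndarray | None = None
    trace_centers: np.ndarray | None = None
    rsc_tau_trace: np.ndarray | None = None
    rsc_tau0_trace: np.ndarray | None = None
    matrix_centers: np.ndarray | None = None
    trend: ratecorr.TrendFit | None = None
    errors: list[str] = field(default_factory=list)


@dataclass
class StudyReport:
    sites: list[SiteResult]
    table: pd.DataFrame
    population: dict
    cluster_tests: dict


def classify_condition(key: tuple) -> str:
    """Map a condition key to its analysis class."""
    kind, value = key
    if kind == "random_motion":
        return "random_motion"
    return "ambiguous" if value == 0 else "unambiguous"


def _site_condition_classes(session: Session) -> dict[str, list[tuple]]:
    classes: dict[str, list[tuple]] = {}
    for key in session.condition_keys():
        classes.setdefault(classify_condition(key), []).append(key)
    return classes


def _whole_trial_rsc(session: Session, keys: list[tuple],
                     unusable: list) -> ratecorr.CorrelationResult | None:
    """Per-condition detrended rSC, pooled over ``keys`` on the Fisher-z scale."""
    zs = []
    ns = []
    for key in keys:
        if key in unusable:
            continue
        idx = session.trial_indices(key)
        su = session.spike_counts("SU", idx)
        mu = session.spike_counts("MU", idx)
        try:
            keep = ratecorr.remove_outlier_trials(su, mu)
        except ValueError:
            continue
        if keep.size < 5:
            continue
        res = ratecorr.compute_rsc(ratecorr.zscore_sliding(su[keep]),
                                   ratecorr.zscore_sliding(mu[keep]))
        if res.valid:
            zs.append(res.fisher_z)
            ns.append(res.n_trials)
    if not zs:
        return None
    z = float(np.mean(zs))
    return ratecorr.CorrelationResult(r_sc=float(ratecorr.fisher_z_inverse(z)),
                                      fisher_z=z, n_trials=int(np.sum(ns)),
                                      window=None)


def _pooled_indices(session: Session, keys: list[tuple], unusable: list) -> np.ndarray:
    out = [session.trial_indices(k) for k in keys if k not in unusable]
    return np.sort(np.concatenate(out)) if out else np.empty(0, int)


def analyse_site(session: Session, config: StudyConfig, seed: int) -> SiteResult:
    """Run every per-site stage; failures are recorded and the site degrades gracefully."""
    site_rep = apply_site_filters(session)
    beh_rep = apply_behavioural_filters(session)
    res = SiteResult(site_id=session.site_id, included=site_rep.included,
                     cp_eligible=beh_rep.cp_eligible)
    if not site_rep.included:
        res.errors.extend(site_rep.reasons)
        return res
    classes = _site_condition_classes(session)
    unusable = site_rep.unusable_conditions

    # --- tuning: cylinder rotation fits on SU and MU -------------------------
    dur_s = session.trial_duration_ms / 1000.0
    cyl_keys = sorted([k for k in session.condition_keys() if k[0] == "cylinder"],
                      key=lambda k: k[1])
    preferred_choice = None
    if len(cyl_keys) >= 3:
        try:
            disp = np.array([k[1] for k in cyl_keys])
            fits = {}
            for unit in ("SU", "MU"):
                means = np.array([session.spike_counts(
                    unit, session.trial_indices(k)).mean() / dur_s for k in cyl_keys])
                fit = tuning.fit_cylinder_tuning(disp, means)
                groups = [session.spike_counts(unit, session.trial_indices(k)) / dur_s
                          for k in cyl_keys]
                fi = tuning.f_index(groups)
                fit.f_index = fi.f_index
                fit.ms_treatment = fi.ms_treatment
                fit.ms_error = fi.ms_error
                fits[unit] = fit
            pair = tuning.classify_pair(fits["SU"], fits["MU"])
            res.strong, res.matched, res.r_signal = pair.strong, pair.matched, pair.r_signal
            res.f_cylinder_su = fits["SU"].f_index
            preferred_choice = "CCW" if fits["SU"].preferred > 0 else "CW"
        except (ValueError, RuntimeError) as exc:
            res.errors.append(f"tuning: {exc}")

    # --- whole-trial rSC per condition class ---------------------------------
    for cls, keys in classes.items():
        r = _whole_trial_rsc(session, keys, unusable)
        if r is not None:
            res.rsc[cls] = r

    # --- CCG / rCCG per condition class --------------------------------------
    for cls, keys in classes.items():
        idx = _pooled_indices(session, keys, unusable)
        if idx.size < 5:
            continue
        try:
            cres = ccgmod.compute_ccg(session.binary_trains("SU", idx),
                                      session.binary_trains("MU", idx),
                                      skip_onset_ms=config.skip_onset_ms)
            res.rccg[cls] = ccgmod.compute_rccg(cres)
        except ValueError as exc:
            res.errors.append(f"ccg[{cls}]: {exc}")

    # --- choice probability on ambiguous trials ------------------------------
    amb_keys = classes.get("ambiguous", [])
    if beh_rep.cp_eligible and amb_keys and preferred_choice is not None:
        idx = _pooled_indices(session, amb_keys, unusable)
        if idx.size >= 2 * config.min_trials_per_choice:
            rates = session.spike_counts("SU", idx) / dur_s
            choices = np.array([session.trials[i].choice for i in idx])
            res.cp = choicemod.cp_significance(
                rates, choices, preferred_choice, n_perm=config.n_perm, seed=seed,
                min_per_group=config.min_trials_per_choice)

    # --- time-courses, lagged matrix, trend (ambiguous condition) ------------
    if amb_keys:
        idx = _pooled_indices(session, amb_keys, unusable)
        if idx.size >= 5:
            centers, r, _ = ratecorr.rsc_timecourse(
                session, idx, window_ms=config.window_ms, step_ms=config.step_ms)
            res.trace_centers = centers
            res.rsc_trace["ambiguous"] = ratecorr.fisher_z(r)
            if preferred_choice is not None:
                counts, c2 = ratecorr.sliding_window_counts(
                    session, idx, "SU", config.window_ms, config.step_ms)
                choices = np.array([session.trials[i].choice for i in idx])
                res.cp_trace = choicemod.cp_timecourse(
                    counts, c2, choices, preferred_choice,
                    min_per_group=config.min_trials_per_choice)
            lag = ratecorr.rsc_matrix(session, idx, bin_ms=config.matrix_bin_ms)
            res.matrix_centers = lag.bin_centers_ms
            res.rsc_tau0_trace = ratecorr.rsc_tau(lag, 0)
            res.rsc_tau_trace = ratecorr.rsc_tau(lag, config.rsc_tau)
            try:
                res.trend = ratecorr.fit_trend(res.rsc_tau_trace, lag.bin_centers_ms,
                                               eval_times_ms=res.trace_centers)
            except ValueError as exc:
                res.errors.append(f"trend: {exc}")
    for cls in ("unambiguous", "random_motion"):
        keys = classes.get(cls, [])
        idx = _pooled_indices(session, keys, unusable)
        if idx.size >= 5:
            centers, r, _ = ratecorr.rsc_timecourse(
                session, idx, window_ms=config.window_ms, step_ms=config.step_ms)
            res.trace_centers = centers if res.trace_centers is None else res.trace_centers
            res.rsc_trace[cls] = ratecorr.fisher_z(r)
    return res


def run_study(sessions: list[Session], config: StudyConfig) -> StudyReport:
    """Analyse a cohort and run the population-level permutation tests."""
    rng = np.random.default_rng(config.seed)
    site_seeds = rng.integers(0, 2 ** 31 - 1, size=len(sessions))
    sites = [analyse_site(s, config, int(seed))
             for s, seed in zip(sessions, site_seeds)]

    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id, "included": s.included,
            "cp_eligible": s.cp_eligible, "strong": s.strong, "matched": s.matched,
            "r_signal": s.r_signal, "f_cylinder_su": s.f_cylinder_su,
            **{f"rsc_{cls}": (r.r_sc if r else np.nan)
               for cls, r in s.rsc.items()},
            **{f"fisher_z_{cls}": (r.fisher_z if r else np.nan)
               for cls, r in s.rsc.items()},
            "cp": s.cp.cp if s.cp else np.nan,
            "cp_p": s.cp.p_value if s.cp else np.nan,
            "trend_derivative": (s.trend.mean_derivative if s.trend else np.nan),
        })
    table = pd.DataFrame(rows)

    population: dict = {"n_sites": len(sites),
                        "n_included": int(sum(s.included for s in sites))}
    for cls in ("ambiguous", "unambiguous", "random_motion"):
        col = f"fisher_z_{cls}"
        if col in table:
            z = table[col].dropna().to_numpy()
            if z.size:
                population[f"mean_rsc_{cls}"] = float(ratecorr.fisher_z_inverse(z.mean()))
                population[f"n_{cls}"] = int(z.size)
    sm = table[(table.get("strong") == True) & (table.get("matched") == True)]  # noqa: E712
    for cls in ("ambiguous", "unambiguous", "random_motion"):
        col = f"fisher_z_{cls}"
        if col in sm and sm[col].notna().any():
            z = sm[col].dropna().to_numpy()
            population[f"mean_rsc_{cls}_strong_matching"] = float(
                ratecorr.fisher_z_inverse(z.mean()))
    cps = table["cp"].dropna().to_numpy() if "cp" in table else np.empty(0)
    if cps.size:
        population["mean_cp"] = float(cps.mean())
        population["n_cp"] = int(cps.size)

    cluster_tests: dict = {}
    seeds = rng.integers(0, 2 ** 31 - 1, size=3)

    # (1) condition comparison of rSC time-courses
    ok = [s for s in sites
          if "ambiguous" in s.rsc_trace and "random_motion" in s.rsc_trace]
    if len(ok) >= 2:
        A = np.stack([s.rsc_trace["ambiguous"] for s in ok])
        B = np.stack([s.rsc_trace["random_motion"] for s in ok])
        cluster_tests["rsc_ambiguous_vs_random"] = stats.cluster_test_conditions(
            A, B, n_perm=config.n_perm, seed=int(seeds[0]))

    # (2) derivative-of-rSC_tau vs CP-time-course correlation field
    ok = [s for s in sites
          if s.trend is not None and s.cp_trace is not None
          and np.all(np.isfinite(s.cp_trace))]
    if len(ok) >= 4:
        D = np.stack([s.trend.derivative for s in ok])
        C = np.stack([s.cp_trace for s in ok])
        try:
            cluster_tests["derivative_vs_cp"] = stats.cluster_test_correlation_field(
                D, C, n_perm=config.n_perm, seed=int(seeds[1]))
        except ValueError:
            pass
        # derivative-sign split of CP traces
        sign = np.array([s.trend.mean_derivative for s in ok])
        rising = sign > 0
        if rising.sum() >= 2 and (~rising).sum() >= 2:
            cluster_tests["cp_by_derivative_sign"] = stats.cluster_test_group_labels(
                C[rising], C[~rising], n_perm=config.n_perm, seed=int(seeds[2]))
            population["mean_cp_rising"] = float(np.nanmean(
                [s.cp.cp for s, r in zip(ok, rising) if r and s.cp]))
            population["mean_cp_decaying"] = float(np.nanmean(
                [s.cp.cp for s, r in zip(ok, rising) if not r and s.cp]))

    return StudyReport(sites=sites, table=table, population=population,
                       cluster_tests=cluster_tests)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def default_cohort_config(seed: int = 0, n_trials: int = 60,
                          n_trials_ambiguous: int | None = None,
                          c_fast: float = 0.85, c_slow: float = 0.10,
                          choice_coupling: float = 0.08,
                          coupling_onset_ms: int = 800,
                          coupling_offset_ms: int = 2000) -> GeneratorConfig:
    """Study conditions for one synthetic site.

    Ambiguous cylinder trials carry fast + slow shared gain plus choice
    coupling; unambiguous cylinder and random-motion trials carry the fast
    gain only.  This is the generative hypothesis the analyses are meant
    to detect: a slow, choice-linked component present only when the
    stimulus is perceptually bistable.  The default strengths put the
    whole-trial correlations near 0.25 for fast-only conditions and near
    0.4 for the ambiguous cylinder, with choice probabilities around
    0.65-0.7 — the regime reported for V5/MT SU/MU pairs.
    """
    conds = (
        Condition("cylinder", 0.0, c_slow=c_slow, choice_coupling=choice_coupling,
                  n_trials=n_trials_ambiguous),   # the key condition is oversampled
        Condition("cylinder", -0.03, c_slow=0.0, choice_coupling=0.0),
        Condition("cylinder", 0.03, c_slow=0.0, choice_coupling=0.0),
        Condition("random_motion", motion_direction_deg=0.0,
                  c_slow=0.0, choice_coupling=0.0),
    )
    return GeneratorConfig(conditions=conds, n_trials_per_condition=n_trials,
                           c_fast=c_fast, c_slow=c_slow,
                           choice_coupling=choice_coupling,
                           coupling_onset_ms=coupling_onset_ms,
                           coupling_offset_ms=coupling_offset_ms,
                           seed=seed)


def simulate_cohort(n_sites: int, seed: int = 0, heterogeneous: bool = True,
                    **kwargs) -> list[Session]:
    """Generate a cohort of sites with varied seeds.

    With ``heterogeneous`` (default), half the sites (alternating) carry
    the choice-linked slow component at full strength and half not at all.
    This across-site contrast is what ties a rising lagged correlation to
    late choice probability at the population level; with
    ``heterogeneous=False`` every site shares the default strengths.
    """
    rng = np.random.default_rng(seed)
    scale = (np.arange(n_sites) % 2 == 0).astype(float) if heterogeneous \
        else np.ones(n_sites)
    base = default_cohort_config(seed=0, **kwargs)
    sessions = []
    for i in range(n_sites):
        site_seed = int(rng.integers(0, 2 ** 31 - 1))
        kw = dict(kwargs)
        kw["choice_coupling"] = base.choice_coupling * scale[i]
        kw["c_slow"] = base.c_slow * scale[i]
        cfg = default_cohort_config(seed=site_seed, **kw)
        cfg = GeneratorConfig(**{**cfg.__dict__, "site_id": f"site{i:03d}"})
        sess, _ = generate_session(cfg)
        sessions.append(sess)
    return sessions
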