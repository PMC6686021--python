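"""Synthetic SU/MU sessions with known correlation structure.

The generator emulates single-electrode recordings from a motion-sensitive
cortical site during a structure-from-motion cylinder task: one single unit
(SU) and the surrounding multi-unit activity (MU) respond to 2 s stimulus
presentations with shared trial-to-trial variability.

Model.  Within each trial the instantaneous rate of a unit is a doubly
stochastic (log-normal gain) modulation of its tuned mean rate::

    lambda(t) = base_rate * tuning(stimulus)
                * exp( drift_m + c_fast*f(t) + c_slow*s(t)
                       + beta*d*w(t)*pref_sign - correction )

where

* ``f(t)`` is a shared "fast" gain — an i.i.d. standard-normal value
  refreshed every 10 ms, producing correlation that accrues within tens of
  milliseconds;
* ``s(t)`` is a shared "slow" gain — a stationary Ornstein–Uhlenbeck
  process with time constant ``tau_slow_ms`` and unit variance, producing
  correlation that keeps accruing out to hundreds of milliseconds;
* ``drift_m`` is a random walk across trials (slow excitability drift,
  common to both units);
* ``d`` in {+1, -1} is the trial's latent decision variable and ``w(t)``
  the indicator of the coupling window: with ``choice_coupling`` (beta)
  positive, firing covaries with the upcoming choice, giving the SU a
  choice probability above 0.5;
* ``correction`` is the analytic log-normal mean correction that keeps the
  expected rate at its nominal value despite the multiplicative gains.

Spikes are drawn per 1 ms bin as Bernoulli(lambda * dt), the
discretization of an inhomogeneous Poisson process at the resolution the
analyses use (chosen over 1 - exp(-lambda dt) so the nominal mean rate is
exact).  The MU is built as four latent sub-units sharing the gains
and merged.  Any MU spike falling in the same 1 ms bin as an SU spike is
deleted, reproducing the mutual exclusivity of spike-sorted SU/MU pairs
(the sorter assigns each waveform to exactly one class), so the raw
cross-correlogram has zero coincidences at lag 0.

Ground truth.  Alongside the session the generator returns the latent
per-trial decision variables, drift, realized gains, and the analytically
expected spike-count correlation per condition derived from the gain
variances (see :func:`expected_rsc`), so every analysis stage can be
checked against known targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import ndtr

from .ratecorr import sliding_zscore_attenuation
from .session import Session, TrialRecord

__all__ = [
    "Condition", "GeneratorConfig", "GroundTruth", "GenerationError",
    "generate_session", "misclassify_spikes", "expected_rsc", "calibrate_c_slow",
]


class GenerationError(ValueError):
    """Raised when a configuration produces an invalid (non-finite) rate."""


@dataclass(frozen=True)
class Condition:
    """One stimulus condition.  Per-condition overrides of the shared-gain
    and choice-coupling strengths allow cohorts in which, e.g., only the
    ambiguous cylinder carries a slow component."""
    stimulus_type: str               # 'cylinder' | 'random_motion'
    disparity_deg: float = 0.0
    motion_direction_deg: float | None = None
    c_fast: float | None = None
    c_slow: float | None = None
    choice_coupling: float | None = None
    n_trials: int | None = None      # overrides n_trials_per_condition


@dataclass(frozen=True)
class GeneratorConfig:
    conditions: tuple[Condition, ...]
    n_trials_per_condition: int = 50
    trial_duration_ms: int = 2000
    bin_ms: int = 1
    base_rate_su: float = 40.0
    base_rate_mu: float = 80.0
    c_fast: float = 0.0
    c_slow: float = 0.0
    tau_slow_ms: float = 300.0
    fast_block_ms: int = 10
    choice_coupling: float = 0.0
    coupling_onset_ms: int = 0
    coupling_offset_ms: int = 2000
    drift_sd: float = 0.0
    # tuning
    pref_direction_deg: float = 0.0
    direction_kappa: float = 1.5
    disparity_midpoint_deg: float = 0.0
    disparity_slope_deg: float = 0.02
    disparity_modulation: float = 0.5   # peak-to-trough rate modulation by rotation sign
    preferred_rotation: int = 1         # +1 = CCW raises rate, -1 = CW
    choice_sigma_deg: float = 0.015     # behavioural sigmoid width
    mu_subunits: int = 4
    site_id: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.base_rate_su <= 0 or self.base_rate_mu <= 0:
            raise GenerationError("base rates must be > 0")
        if min(self.c_fast, self.c_slow, self.choice_coupling) < 0:
            raise GenerationError("c_fast, c_slow, choice_coupling must be >= 0")
        if not (0 <= self.coupling_onset_ms < self.coupling_offset_ms
                <= self.trial_duration_ms):
            raise GenerationError(
                "need 0 <= coupling_onset_ms < coupling_offset_ms <= trial_duration_ms")
        if self.drift_sd < 0 or self.tau_slow_ms <= 0:
            raise GenerationError("drift_sd >= 0 and tau_slow_ms > 0 required")
        if not self.conditions:
            raise GenerationError("at least one condition required")
        if self.bin_ms != 1:
            raise GenerationError("only 1 ms bins are supported")


@dataclass
class GroundTruth:
    """Latents of a generated session.  Analysis modules never read this."""
    target_rsc: dict              # condition key -> analytically expected count correlation
    target_rsc_detrended: dict    # the same, times the sliding-z estimator attenuation
    decision: np.ndarray          # per trial, in session order; 0 = no choice
    drift: np.ndarray             # per-trial log-rate drift
    mean_gain: np.ndarray         # per-trial mean of exp(shared log-gain)
    condition_of_trial: list      # condition key per trial


# ---------------------------------------------------------------------------
# Analytic expected rSC from the gain variances
# ---------------------------------------------------------------------------

def _pair_count_gain_variance(c_fast: float, c_slow: float, tau_slow_ms: float,
                              T: int, fast_block_ms: int = 10) -> float:
    """Relative variance V of the trial-integrated gain.

    For corrected log-normal gains the covariance of the integrated gain
    between two fully shared streams is ``R_j * R_k * V`` with

        V = (1/T^2) sum_{t,u} [ exp(cov(x_t, x_u)) - 1 ],

    where cov(x_t, x_u) = c_slow^2 exp(-|t-u|/tau) + c_fast^2 [same block].
    Evaluated exactly by counting ordered (t, u) pairs per lag.
    """
    d = np.arange(T, dtype=float)
    n_tot = 2.0 * (T - d)
    n_tot[0] = T
    B = fast_block_ms
    n_same = np.zeros(T)
    within = d < B
    n_same[within] = 2.0 * (T // B) * (B - d[within])
    n_same[0] = T
    cov_slow = c_slow ** 2 * np.exp(-d / tau_slow_ms)
    v_same = np.expm1(cov_slow + c_fast ** 2)
    v_diff = np.expm1(cov_slow)
    total = np.sum(n_same * v_same + (n_tot - n_same) * v_diff)
    return float(total) / T ** 2


def expected_rsc(rate_su: float, rate_mu: float, c_fast: float, c_slow: float,
                 tau_slow_ms: float, T: int = 2000, fast_block_ms: int = 10,
                 exclusivity: bool = True) -> float:
    """Analytic spike-count correlation implied by the shared gains.

    ``rate_su``/``rate_mu`` are the tuned mean rates in spikes/s.  With
    per-bin firing probabilities ``a*g(t)`` and ``b*g(t)`` driven by the
    shared corrected log-normal gain ``g`` (E[g] = 1, E[g^2] = kappa2),
    the trial counts have

        Cov    ~ a b (1 - 2 a kappa2) V T^2  -  a b kappa2 T
        Var_su ~ R_su - a^2 kappa2 T + a^2 V T^2
        Var_mu ~ R_mu' - b^2 kappa2 T + b^2 (1 - 2 a kappa2)^2 V T^2

    where V is the integrated gain covariance factor
    (:func:`_pair_count_gain_variance`).  The ``exclusivity`` terms are
    the first-order corrections for the deletion of MU spikes coincident
    with SU spikes: the deletion thins the MU (R_mu' = R_mu (1 - a
    kappa2)), contributes the per-bin anticorrelation ``-a b kappa2 T``,
    and damps the MU's gain sensitivity (deleted coincidences scale with
    g^2, so high-gain trials lose more MU spikes).  Binarization at 1 ms
    (at most one spike per bin) enters as the OR-merge thinning of the
    four MU sub-units, b -> b (1 - 3/8 b kappa2), and the ``- kappa2 T``
    sub-Poisson variance terms.
    """
    V = _pair_count_gain_variance(c_fast, c_slow, tau_slow_ms, T, fast_block_ms)
    kappa2 = math.exp(c_fast ** 2 + c_slow ** 2)
    a = rate_su / 1000.0                       # per 1 ms bin; Bernoulli(lambda dt), exact mean
    b = rate_mu / 1000.0
    b = b * (1.0 - 0.375 * b * kappa2)         # OR-merge of 4 sub-units caps at one spike/bin
    if not exclusivity:
        cov = a * b * V * T ** 2
        var_su = a * T - a ** 2 * kappa2 * T + a ** 2 * V * T ** 2
        var_mu = b * T - b ** 2 * kappa2 * T + b ** 2 * V * T ** 2
        return cov / math.sqrt(var_su * var_mu)
    damp = 1.0 - 2.0 * a * kappa2
    R_mu_eff = b * T * (1.0 - a * kappa2)
    cov = a * b * damp * V * T ** 2 - a * b * kappa2 * T
    var_su = a * T - a ** 2 * kappa2 * T + a ** 2 * V * T ** 2
    var_mu = R_mu_eff - b ** 2 * kappa2 * T + (b * damp) ** 2 * V * T ** 2
    return cov / math.sqrt(var_su * var_mu)


def calibrate_c_slow(target_rsc: float, rate_su: float, rate_mu: float,
                     c_fast: float = 0.0, tau_slow_ms: float = 300.0,
                     T: int = 2000) -> float:
    """Slow-gain strength whose analytic rSC equals ``target_rsc``.

    Inverts :func:`expected_rsc` in ``c_slow`` by bisection.  Raises if the
    target is not reachable below c_slow = 2 (far outside the physiological
    regime this generator emulates).
    """
    lo = expected_rsc(rate_su, rate_mu, c_fast, 0.0, tau_slow_ms, T)
    if target_rsc <= lo:
        raise ValueError(f"target rSC {target_rsc} already exceeded at c_slow=0 ({lo:.3f})")
    return float(brentq(
        lambda c: expected_rsc(rate_su, rate_mu, c_fast, c, tau_slow_ms, T) - target_rsc,
        1e-6, 2.0, xtol=1e-8))


# ---------------------------------------------------------------------------
# Tuning factors
# ---------------------------------------------------------------------------

def _tuning_factor(cfg: GeneratorConfig, cond: Condition) -> float:
    """Multiplicative rate modulation of this condition (1 at the neutral point)."""
    if cond.stimulus_type == "random_motion":
        if cond.motion_direction_deg is None:
            return 1.0
        dtheta = math.radians(cond.motion_direction_deg - cfg.pref_direction_deg)
        return math.exp(cfg.direction_kappa * (math.cos(dtheta) - 1.0))
    m = cfg.disparity_modulation
    x = (cond.disparity_deg - cfg.disparity_midpoint_deg) / cfg.disparity_slope_deg
    p = ndtr(cfg.preferred_rotation * x)
    return 1.0 - m / 2.0 + m * p


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Simulate one recording session; bit-identical for identical (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.trial_duration_ms
    B = config.fast_block_ms
    n_blocks = -(-T // B)

    # interleaved trial order, as in the experiment
    reps = [c.n_trials if c.n_trials is not None else config.n_trials_per_condition
            for c in config.conditions]
    cond_of_trial = np.repeat(np.arange(len(config.conditions)), reps)
    cond_of_trial = rng.permutation(cond_of_trial)
    n_trials = cond_of_trial.size

    drift = np.cumsum(rng.normal(0.0, config.drift_sd, size=n_trials))
    drift_corr = np.arange(1, n_trials + 1) * config.drift_sd ** 2 / 2.0

    t_ms = np.arange(T)
    w = ((t_ms >= config.coupling_onset_ms)
         & (t_ms < config.coupling_offset_ms)).astype(float)

    rho = math.exp(-1.0 / config.tau_slow_ms)
    innov_sd = math.sqrt(1.0 - rho ** 2)

    trials: list[TrialRecord] = []
    su_spk: list[np.ndarray] = []
    mu_spk: list[np.ndarray] = []
    decision = np.zeros(n_trials)
    mean_gain = np.zeros(n_trials)

    for m in range(n_trials):
        cond = config.conditions[cond_of_trial[m]]
        cf = config.c_fast if cond.c_fast is None else cond.c_fast
        cs = config.c_slow if cond.c_slow is None else cond.c_slow
        beta = (config.choice_coupling if cond.choice_coupling is None
                else cond.choice_coupling)

        # shared gain processes
        fast = np.repeat(rng.standard_normal(n_blocks), B)[:T]
        # stationary OU as an AR(1): y[0] ~ N(0,1), y[t] = rho*y[t-1] + innov
        impulse = np.concatenate(([rng.standard_normal()],
                                  rng.standard_normal(T - 1) * innov_sd))
        slow = lfilter([1.0], [1.0, -rho], impulse)

        if cond.stimulus_type == "cylinder":
            p_ccw = ndtr(cond.disparity_deg / config.choice_sigma_deg)
            d = 1 if rng.random() < p_ccw else -1
            choice = "CCW" if d == 1 else "CW"
            if cond.disparity_deg == 0:
                rewarded = bool(rng.random() < 0.5)   # random reward on ambiguous trials
            else:
                rewarded = (d == 1) == (cond.disparity_deg > 0)
        else:
            d, choice, rewarded = 0, "none", True
        decision[m] = d

        x = cf * fast + cs * slow + drift[m] - drift_corr[m]
        corr = cf ** 2 / 2.0 + cs ** 2 / 2.0
        if d != 0 and beta > 0:
            x = x + beta * d * config.preferred_rotation * w
            corr = corr + np.log(np.cosh(beta)) * w
        log_gain = x - corr
        mean_gain[m] = float(np.exp(log_gain).mean())

        tune = _tuning_factor(config, cond)
        lam_su = config.base_rate_su * tune * np.exp(log_gain) / 1000.0  # per 1 ms bin
        if not np.all(np.isfinite(lam_su)):
            raise GenerationError(
                "non-finite rate; check drift_sd / c_fast / c_slow / choice_coupling")
        # Bernoulli per 1 ms bin with p = lambda*dt: the discretization whose
        # mean rate is exactly nominal (rates here keep p << 1)
        su_bin = rng.random(T) < np.clip(lam_su, 0.0, 1.0)

        lam_sub = (config.base_rate_mu / config.mu_subunits) * tune \
            * np.exp(log_gain) / 1000.0
        mu_bin = (rng.random((config.mu_subunits, T))
                  < np.clip(lam_sub, 0.0, 1.0)).any(axis=0)
        mu_bin &= ~su_bin              # sorter exclusivity: SU wins the bin

        su_spk.append(np.flatnonzero(su_bin) + 0.5)
        mu_spk.append(np.flatnonzero(mu_bin) + 0.5)
        trials.append(TrialRecord(
            trial_id=m, stimulus_type=cond.stimulus_type,
            disparity_deg=cond.disparity_deg,
            motion_direction_deg=cond.motion_direction_deg,
            choice=choice, rewarded=rewarded))

    session = Session(site_id=config.site_id, trial_duration_ms=T,
                      trials=trials, su_spikes=su_spk, mu_spikes=mu_spk)

    targets: dict = {}
    keys = []
    for cond in config.conditions:
        cf = config.c_fast if cond.c_fast is None else cond.c_fast
        cs = config.c_slow if cond.c_slow is None else cond.c_slow
        tune = _tuning_factor(config, cond)
        key = (("cylinder", float(cond.disparity_deg))
               if cond.stimulus_type == "cylinder"
               else ("random_motion", cond.motion_direction_deg))
        keys.append(key)
        targets[key] = expected_rsc(
            config.base_rate_su * tune, config.base_rate_mu * tune,
            cf, cs, config.tau_slow_ms, T, config.fast_block_ms)
    att = sliding_zscore_attenuation()
    gt = GroundTruth(target_rsc=targets,
                     target_rsc_detrended={k: v * att for k, v in targets.items()},
                     decision=decision, drift=drift, mean_gain=mean_gain,
                     condition_of_trial=[keys[i] for i in cond_of_trial])
    return session, gt


# ---------------------------------------------------------------------------
# Spike-sorting misclassification
# ---------------------------------------------------------------------------

def misclassify_spikes(session: Session, fraction: float,
                       seed: int = 0) -> tuple[Session, int]:
    """Swap a fraction of spikes between the SU and MU trains.

    Emulates deliberate sorting errors: per trial, ``round(fraction * N)``
    uniformly chosen spikes of each train are re-assigned to the other
    train.  A moved spike landing in an occupied 1 ms bin of its
    destination is dropped; the number of such collisions is returned (the
    per-trial spike count is conserved up to them).
    """
    if not (0.0 <= fraction <= 0.5):
        raise ValueError(f"fraction must be in [0, 0.5], got {fraction}")
    rng = np.random.default_rng(seed)
    collisions = 0
    new_su, new_mu = [], []
    for su, mu in zip(session.su_spikes, session.mu_spikes):
        n_su_mv = round(fraction * su.size)
        n_mu_mv = round(fraction * mu.size)
        su_mv = rng.choice(su.size, size=n_su_mv, replace=False) if n_su_mv else np.empty(0, int)
        mu_mv = rng.choice(mu.size, size=n_mu_mv, replace=False) if n_mu_mv else np.empty(0, int)
        su_keep = np.delete(su, su_mv)
        mu_keep = np.delete(mu, mu_mv)
        su_out, c1 = _insert(su_keep, mu[mu_mv])
        mu_out, c2 = _insert(mu_keep, su[su_mv])
        collisions += c1 + c2
        new_su.append(su_out)
        new_mu.append(mu_out)
    out = Session(site_id=session.site_id,
                  trial_duration_ms=session.trial_duration_ms,
                  trials=list(session.trials), su_spikes=new_su, mu_spikes=new_mu)
    return out, collisions


def _insert(train: np.ndarray, incoming: np.ndarray) -> tuple[np.ndarray, int]:
    occupied = set(np.floor(train).astype(int).tolist())
    kept = []
    dropped = 0
    for t in np.sort(incoming):
        b = int(math.floor(t))
        if b in occupied:
            dropped += 1
        else:
            occupied.add(b)
            kept.append(t)
    return np.sort(np.concatenate([train, np.asarray(kept, float)])), dropped
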