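"""Trial-structured paired SU/MU spike data: container, CSV round-trip, inclusion filters.

A recording *site* holds one isolated single unit (SU) and the residual
multi-unit activity (MU) from the same electrode, recorded over a sequence
of trials.  Each trial presents either a structure-from-motion cylinder at
some binocular disparity (negative = clockwise rotation, positive =
counter-clockwise) or a zero-net-motion random-dot stimulus, and for
cylinder trials records the subject's perceptual choice.

On disk a session is a directory with two CSV files:

``trials.csv``
    columns ``site_id, trial_id, stimulus_type, disparity_deg,
    motion_direction_deg, choice, rewarded``
``spikes.csv``
    columns ``trial_id, unit, time_ms`` with ``unit`` in {SU, MU} and
    ``time_ms`` in milliseconds from stimulus onset, three decimals.

Spike times live on the half-open interval ``[0, trial_duration_ms)`` and
are sorted ascending within each trial.  SU and MU never share the same
integer-millisecond bin (the SU is isolated *out of* the MU, so a spike is
one or the other).  Trial order is preserved as recorded — the sliding
trial z-score downstream depends on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STIMULUS_TYPES = ("cylinder", "random_motion")
CHOICES = ("CW", "CCW", "none")

#: minimum SU mean rate (spikes/s) for a site to be analysed
MIN_SITE_RATE = 10.0
#: minimum surviving trials per condition
MIN_TRIALS_PER_CONDITION = 5
#: behavioural criteria: fraction correct at max disparity, max choice bias
MIN_PCT_CORRECT = 0.80
MAX_CHOICE_BIAS = 0.80


class SessionValidationError(ValueError):
    """A session violates a structural invariant."""


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    stimulus_type: str
    disparity_deg: float
    motion_direction_deg: float | None
    choice: str
    rewarded: bool

    def __post_init__(self) -> None:
        if self.stimulus_type not in STIMULUS_TYPES:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown stimulus_type {self.stimulus_type!r}")
        if self.choice not in CHOICES:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown choice {self.choice!r}")
        if (self.choice == "none") != (self.stimulus_type == "random_motion"):
            raise SessionValidationError(
                f"trial {self.trial_id}: choice must be 'none' iff stimulus is "
                f"random_motion (got {self.stimulus_type!r}, {self.choice!r})")


def condition_key(trial: TrialRecord) -> tuple:
    """Hashable stimulus-condition identity of a trial.

    Cylinder trials group by disparity; random-motion trials by motion
    direction.  Correlations and CPs are computed over repeats of one
    condition.
    """
    if trial.stimulus_type == "cylinder":
        return ("cylinder", float(trial.disparity_deg))
    return ("random_motion", trial.motion_direction_deg)


@dataclass
class Session:
    site_id: str
    trial_duration_ms: int
    trials: list[TrialRecord]
    su_spikes: list[np.ndarray]
    mu_spikes: list[np.ndarray]

    def __post_init__(self) -> None:
        self.su_spikes = [np.asarray(s, dtype=float) for s in self.su_spikes]
        self.mu_spikes = [np.asarray(s, dtype=float) for s in self.mu_spikes]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        """Check every structural invariant; raise SessionValidationError on the first failure."""
        T = self.trial_duration_ms
        if not (len(self.trials) == len(self.su_spikes) == len(self.mu_spikes)):
            raise SessionValidationError("trial / spike-list length mismatch")
        for tr, su, mu in zip(self.trials, self.su_spikes, self.mu_spikes):
            for name, times in (("SU", su), ("MU", mu)):
                if times.size == 0:
                    continue
                if times.min() < 0 or times.max() >= T:
                    raise SessionValidationError(
                        f"trial {tr.trial_id}: {name} spike time outside [0, {T})")
                if np.any(np.diff(times) < 0):
                    raise SessionValidationError(
                        f"trial {tr.trial_id}: {name} spike times not sorted")
            if su.size and mu.size and np.intersect1d(
                    np.floor(su).astype(int), np.floor(mu).astype(int)).size:
                raise SessionValidationError(
                    f"trial {tr.trial_id}: SU and MU share a 1 ms bin")

    # -- convenience accessors -------------------------------------------------

    def condition_keys(self) -> list[tuple]:
        """Distinct condition keys in first-appearance order."""
        seen: dict[tuple, None] = {}
        for tr in self.trials:
            seen.setdefault(condition_key(tr), None)
        return list(seen)

    def trial_indices(self, key: tuple | None = None) -> np.ndarray:
        """Indices (in recorded order) of trials matching ``key``; all trials if None."""
        if key is None:
            return np.arange(self.n_trials)
        return np.array([i for i, tr in enumerate(self.trials)
                         if condition_key(tr) == key], dtype=int)

    def spike_counts(self, unit: str, indices: Sequence[int] | None = None,
                     window_ms: tuple[float, float] | None = None) -> np.ndarray:
        """Per-trial spike counts for ``unit`` in {SU, MU}, optionally windowed."""
        trains = self._trains(unit)
        if indices is None:
            indices = range(self.n_trials)
        if window_ms is None:
            return np.array([trains[i].size for i in indices], dtype=float)
        a, b = window_ms
        return np.array(
            [np.count_nonzero((trains[i] >= a) & (trains[i] < b)) for i in indices],
            dtype=float)

    def binned_counts(self, unit: str, indices: Sequence[int],
                      edges_ms: np.ndarray) -> np.ndarray:
        """(n_trials, n_bins) spike-count matrix over the bin ``edges_ms``."""
        trains = self._trains(unit)
        return np.stack([np.histogram(trains[i], bins=edges_ms)[0].astype(float)
                         for i in indices])

    def binary_trains(self, unit: str, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_trials, T) binary matrix at 1 ms resolution (multiple spikes in a bin cap at 1)."""
        trains = self._trains(unit)
        if indices is None:
            indices = range(self.n_trials)
        T = self.trial_duration_ms
        out = np.zeros((len(list(indices)), T), dtype=np.uint8)
        for row, i in enumerate(indices):
            bins = np.floor(trains[i]).astype(int)
            out[row, bins] = 1
        return out

    def _trains(self, unit: str) -> list[np.ndarray]:
        if unit == "SU":
            return self.su_spikes
        if unit == "MU":
            return self.mu_spikes
        raise ValueError(f"unit must be 'SU' or 'MU', got {unit!r}")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_session(session: Session, path: str | Path) -> None:
    """Write ``trials.csv`` + ``spikes.csv`` into directory ``path`` (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trows = []
    srows: list[tuple[int, str, float]] = []
    for tr, su, mu in zip(session.trials, session.su_spikes, session.mu_spikes):
        trows.append({
            "site_id": session.site_id,
            "trial_id": tr.trial_id,
            "stimulus_type": tr.stimulus_type,
            "disparity_deg": tr.disparity_deg,
            "motion_direction_deg": ("" if tr.motion_direction_deg is None
                                     else tr.motion_direction_deg),
            "choice": tr.choice,
            "rewarded": tr.rewarded,
        })
        srows.extend((tr.trial_id, "SU", t) for t in su)
        srows.extend((tr.trial_id, "MU", t) for t in mu)
    pd.DataFrame(trows).to_csv(path / "trials.csv", index=False)
    sdf = pd.DataFrame(srows, columns=["trial_id", "unit", "time_ms"])
    sdf.to_csv(path / "spikes.csv", index=False, float_format="%.3f")
    meta = {"site_id": session.site_id, "trial_duration_ms": session.trial_duration_ms}
    (path / "session.json").write_text(json.dumps(meta))


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`; validates on load."""
    path = Path(path)
    meta = json.loads((path / "session.json").read_text())
    try:
        tdf = pd.read_csv(path / "trials.csv",
                          dtype={"choice": str, "stimulus_type": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SessionValidationError(f"{path / 'trials.csv'}: {exc}") from exc
    sdf = pd.read_csv(path / "spikes.csv")
    trials, su, mu = [], [], []
    spikes_by_trial = {tid: g for tid, g in sdf.groupby("trial_id")}
    for _, row in tdf.iterrows():
        mdir = row["motion_direction_deg"]
        mdir = None if pd.isna(mdir) else float(mdir)
        trials.append(TrialRecord(
            trial_id=int(row["trial_id"]),
            stimulus_type=row["stimulus_type"],
            disparity_deg=float(row["disparity_deg"]),
            motion_direction_deg=mdir,
            choice=row["choice"],
            rewarded=bool(row["rewarded"]),
        ))
        g = spikes_by_trial.get(int(row["trial_id"]))
        if g is None:
            su.append(np.empty(0)); mu.append(np.empty(0))
        else:
            su.append(np.sort(g.loc[g["unit"] == "SU", "time_ms"].to_numpy(float)))
            mu.append(np.sort(g.loc[g["unit"] == "MU", "time_ms"].to_numpy(float)))
    sess = Session(site_id=str(meta["site_id"]),
                   trial_duration_ms=int(meta["trial_duration_ms"]),
                   trials=trials, su_spikes=su, mu_spikes=mu)
    sess.validate()
    return sess


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

@dataclass
class SiteFilterReport:
    """Outcome of applying site/trial inclusion rules.  Report-only: the
    session itself is never mutated."""
    included: bool
    reasons: list[str] = field(default_factory=list)
    trial_counts_before: dict = field(default_factory=dict)
    trial_counts_after: dict = field(default_factory=dict)
    retained_trials: np.ndarray | None = None
    unusable_conditions: list = field(default_factory=list)
    mu_rate_low: bool = False
    # behavioural-filter extras (None when not assessed)
    cp_eligible: bool | None = None
    pct_correct_max_disparity: float | None = None
    ambiguous_choice_fraction: float | None = None


def apply_site_filters(session: Session) -> SiteFilterReport:
    """Site/trial inclusion rules for correlation analyses.

    A site is excluded when the SU mean rate across trials is below
    10 spikes/s.  Trials in which either stream fired no spike are dropped
    (a zero-count trial breaks the sliding z-score).  Any condition left
    with fewer than five trials is flagged unusable; the site survives for
    its other conditions.  MU rate below 10 spikes/s is flagged, not
    excluding.
    """
    dur_s = session.trial_duration_ms / 1000.0
    su_counts = session.spike_counts("SU")
    mu_counts = session.spike_counts("MU")
    su_rate = su_counts.mean() / dur_s if session.n_trials else 0.0

    reasons = []
    included = True
    if su_rate < MIN_SITE_RATE:
        included = False
        reasons.append(f"SU mean rate {su_rate:.2f} spikes/s < {MIN_SITE_RATE}")

    keep = (su_counts >= 1) & (mu_counts >= 1)
    retained = np.nonzero(keep)[0]

    before: dict = {}
    after: dict = {}
    for i, tr in enumerate(session.trials):
        key = condition_key(tr)
        before[key] = before.get(key, 0) + 1
        if keep[i]:
            after[key] = after.get(key, 0) + 1
    unusable = [k for k in before if after.get(k, 0) < MIN_TRIALS_PER_CONDITION]
    if unusable and len(unusable) == len(before):
        included = False
        reasons.append("no condition retains >= 5 trials")

    rep = SiteFilterReport(included=included, reasons=reasons,
                           trial_counts_before=before, trial_counts_after=after,
                           retained_trials=retained, unusable_conditions=unusable)
    rep.mu_rate_low = bool(mu_counts.mean() / dur_s < MIN_SITE_RATE) if session.n_trials else True
    return rep


def apply_behavioural_filters(session: Session) -> SiteFilterReport:
    """CP-eligibility from behaviour on cylinder trials.

    Eligible iff the subject scored above 80% correct at the largest
    absolute disparity tested AND neither choice exceeded 80% of the
    ambiguous (zero-disparity) cylinder trials.  With no ambiguous trials
    eligibility is undefined (``cp_eligible=None``) and reported as such.
    """
    cyl = [tr for tr in session.trials if tr.stimulus_type == "cylinder"]
    rep = SiteFilterReport(included=True)
    if not cyl:
        rep.cp_eligible = None
        rep.reasons.append("no cylinder trials")
        return rep
    disp = np.array([tr.disparity_deg for tr in cyl])
    nonzero = np.abs(disp) > 0
    ambiguous = [tr for tr, nz in zip(cyl, nonzero) if not nz]

    if nonzero.any():
        dmax = np.abs(disp[nonzero]).max()
        at_max = [tr for tr in cyl if abs(tr.disparity_deg) == dmax]
        correct = [(tr.choice == "CCW") == (tr.disparity_deg > 0) for tr in at_max]
        pct = float(np.mean(correct))
        rep.pct_correct_max_disparity = pct
        if not pct > MIN_PCT_CORRECT:
            rep.cp_eligible = False
            rep.reasons.append(
                f"{pct:.0%} correct at max disparity +/-{dmax:g} deg (needs > 80%)")
    else:
        rep.reasons.append("no unambiguous cylinder trials; performance criterion not assessable")

    if not ambiguous:
        rep.cp_eligible = None
        rep.reasons.append("no ambiguous cylinder trials; eligibility undefined")
        return rep
    frac_ccw = float(np.mean([tr.choice == "CCW" for tr in ambiguous]))
    rep.ambiguous_choice_fraction = frac_ccw
    if max(frac_ccw, 1 - frac_ccw) > MAX_CHOICE_BIAS:
        rep.cp_eligible = False
        rep.reasons.append(
            f"choice bias {max(frac_ccw, 1 - frac_ccw):.0%} on ambiguous trials (limit 80%)")
    if rep.cp_eligible is None:
        rep.cp_eligible = True
    return rep
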