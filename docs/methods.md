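# Methods

This note documents the statistical model behind the synthetic sessions,
the estimators, the numerical and design choices that were genuinely
open, and the limits of what the synthetic validation shows.

## The generative model

A session is a sequence of 2 s trials at 1 ms resolution from one
recording site: one single unit (SU) and one multi-unit stream (MU) that
share their trial-to-trial variability.  Within a trial the rate of each
unit is a log-normal gain modulation of its tuned mean:

    λ(t) = base_rate · tuning(stimulus)
           · exp( drift_m + c_fast·f(t) + c_slow·s(t) + β·d·w(t)·p − corr )

- **f(t)** — shared fast gain: i.i.d. N(0,1), refreshed every 10 ms
  (`fast_block_ms`).  Produces correlation that is complete within tens
  of milliseconds of lag; the 10 ms refresh puts the resulting rCCG
  plateau in the few-tens-of-ms range typical of bottom-up shared input.
- **s(t)** — shared slow gain: stationary Ornstein–Uhlenbeck process
  with unit variance and time constant `tau_slow_ms` (default 300 ms,
  i.e. "hundreds of milliseconds").  Simulated exactly as an AR(1) with
  ρ = exp(−1/τ).
- **drift_m** — random walk across trials with step SD `drift_sd`,
  shared by both units (excitability drift is common-source).  The
  sliding-trial z-score must remove it; tests check that it does.
- **d ∈ {±1}** — the trial's latent decision.  For cylinder trials
  P(d = +1) = Φ(disparity / σ_choice) with σ_choice = 0.015°, so ±0.03°
  disparity yields ~98% correct choices and 0° a near-even split — the
  regime the behavioural inclusion filters (>80% correct at max
  disparity, ≤80% choice bias on ambiguous trials) are designed for.
  The recorded choice is d's sign; random-motion trials have d = 0 and
  no choice.  β (`choice_coupling`) couples d to the rate inside the
  window `w(t)` = [coupling_onset, coupling_offset), with `p` the unit's
  preferred rotation sign.
- **corr** — the exact log-normal mean corrections (c²/2 per Gaussian
  gain, log cosh β inside the coupling window, cumulative drift-variance
  correction), keeping the expected rate at its nominal value.

Spikes are Bernoulli per 1 ms bin with p = λΔ (the discretization of an
inhomogeneous Poisson process whose nominal mean rate is exact; rates
here keep p ≤ 0.1).  The MU is the OR-merge of four sub-units sharing
the gains.  MU spikes landing in a bin occupied by an SU spike are
deleted, reproducing the mutual exclusivity of a spike sorter's output:
the raw cross-correlogram of a generated pair has *zero* coincidences at
lag 0, and the rCCG curve starts below zero at small τ.

Defaults: SU 40 spikes/s, MU 80 spikes/s — mid-range extrastriate rates
with the MU pooling several neurons.

### Analytic correlation targets

For fully shared corrected log-normal gains, the count covariance is
`R_su·R_mu·V` with `V = (1/T²) ΣΣ (exp(cov(x_t,x_u)) − 1)`, evaluated
exactly by counting bin pairs per lag (`_pair_count_gain_variance`).
`expected_rsc` adds the first-order corrections for the 1 ms cap on the
merged MU (b → b(1 − 3/8·b·κ₂)), and for the exclusivity deletion: MU
thinning (1 − a·κ₂), a per-bin anticorrelation term −a·b·κ₂·T, and a
damping (1 − 2a·κ₂) of the MU's gain sensitivity because high-gain
trials lose more coincident spikes.  Against direct simulation at 12,000
trials the resulting target is accurate to ±0.005 over the 0.1–0.3
range.  `calibrate_c_slow` inverts the map by bisection to hit a
requested rSC.

The detrended estimator is *not* unbiased for this target: dividing each
trial by an SD estimated from its m = 10 neighbours shrinks the expected
Pearson r by (ν−2)/2·[Γ((ν−1)/2)/Γ(ν/2)]² with ν = m−1, ≈ 0.931 for the
default window (`sliding_zscore_attenuation`; derivation assumes
near-normal responses and independent SD estimates — their coupling is
O(r²)).  `GroundTruth` therefore carries both `target_rsc` (the count
correlation) and `target_rsc_detrended` (what the pipeline's estimator
should report); the measured attenuation matches the formula to three
decimals.  The bias cancels in any comparison between conditions
analysed identically.

## Estimators

**rSC** — spikes counted over the window, 3 SD outlier trials removed
once per condition on whole-trial counts (the same retained set is
reused by all time-resolved analyses), sliding z-score with the current
trial excluded and truncated windows at the sequence edges (dropping 10
trials per condition is untenable at realistic trial counts), σ = 0 ⇒
z = 0 so constant stretches contribute nothing but keep n fixed.
Fisher z for all group statistics; site averages are computed on z and
back-transformed for display.

**Time-courses** — 100 ms sliding windows (default step 1 ms; the step
only affects sampling of the trace, not the estimator, and coarser steps
are used where a full-resolution trace adds nothing), detrended within
each window.  Gaussian display smoothing (30 ms SD) exists but is never
applied before statistics.

**Lagged matrix** — 20 non-overlapping 100 ms bins; entry (i, j) is the
detrended correlation of SU bin i with MU bin j.  rSC_τ=0 is the
diagonal; rSC_τ=4 averages the entries at offsets 1–4 along both the row
and the column (the matrix is not symmetric, and lead/lag with respect
to bin i appears in both), excluding the diagonal and clipping at the
edges.  A quadratic in trial time is fit to rSC_τ by least squares; its
exact derivative 2at + b is the trial-time-resolved rising/decaying
index, summarised by its value at the trial midpoint.

**CCG / rCCG** — binary trains (counts capped at 1 per ms).  FFT-based
cross-correlations; the shift predictor is computed from the PSTH
cross-correlation form, which equals the mean over all M(M−1)
cross-trial pairings (loop-verified), and is subtracted from CCGs and
ACGs alike after identical normalization.  `compute_rccg` integrates the
*triangular-weighted* corrected correlograms: summed over all lags these
are exactly (M−1)·sample covariance and (M−1)·sample variances, so
rCCG at full lag equals the Pearson correlation of the spike counts to
machine precision; the Θ-normalized integrand would instead amplify the
noise of near-full-trial lags by up to a factor T.  For τ ≪ T the two
conventions agree to O(τ/T), which covers the 40/400 ms plateau
diagnostics.  An `skip_onset_ms` option (default 0) excludes the onset
transient; with the stationary generator it makes no difference.

**CP** — midrank Mann–Whitney, exactly the ROC area with 0.5 per tie.
The preferred choice comes from the rotation-tuning fit, never from the
choice data (refitting would bias CP away from 0.5 by selection).  A
floor of 5 trials per choice group avoids degenerate ROC areas.
Significance: choice labels permuted, one-sided
p = (1 + #{CP_perm ≥ CP_obs})/(n_perm + 1).

**Tuning** — fits on square-root rates (variance-stabilising for
near-Poisson counts).  Direction: baseline + amplitude·exp(κ(cosθ−1)),
8 preferred-direction starts; rotation: baseline + amplitude·Φ((x−mid)/sd),
sign-and-scale start grid; Nelder–Mead throughout, a fit converging from
no start is flagged.  The F-index is MS_treatment/(MS_error+MS_treatment)
from the one-way ANOVA on sqrt rates (a pure-rounding MS_treatment below
1e−18·grand² counts as zero).  A pair is "strong" when both F-indices
exceed 0.1 and "matching" when preferred rotations share a sign
(cylinder) or fitted preferred directions lie within 90° (direction);
r_signal is the Pearson correlation of the raw mean tuning vectors.
Variance explained is reported, not used as a filter.

**Cluster tests** — pointwise two-sided p < 0.05 defines clusters
(1D contiguity, 2D 4-connectivity); cluster size is mass (Σ|statistic|)
by default with extent available, since "size" is ambiguous between the
two and mass is the common choice.  The null permutes whichever label is
exchangeable under the hypothesis: condition within site, site-to-value
assignment across sites, or choice across trials.  Cluster
p = (1 + #{max_null ≥ size})/(n_perm + 1); measured family-wise false
positive rate 6 ± 1% at nominal 5% (500 null simulations).

**Partial correlation** — residuals of x and y on [1, control],
correlated; p from t with n−3 df; a numerically zero residual (control
explains the variable fully) returns r = 0 by convention, flagged.

## Inclusion filters

Sites with SU mean rate < 10 spikes/s are excluded; trials with zero
spikes in either stream are dropped (a zero vector breaks the z-score);
conditions with < 5 surviving trials are unusable (correlations are
computed over repeats within a condition, so the floor applies per
condition).  An MU below 10 spikes/s is flagged but not excluding.  CP
eligibility additionally requires >80% correct at the largest |disparity|
and neither choice taken on >80% of ambiguous trials; with no ambiguous
trials eligibility is undefined and reported as such.  Filters are pure
and idempotent.

## Study pipeline and the synthetic cohort

`pipeline.run_study` orders the stages: filters → tuning and
strong/matching classification → whole-trial rSC per condition class
(ambiguous = 0° cylinder; unambiguous = non-zero disparities, pooled per
site on the Fisher-z scale; random motion) → CCG/rCCG per class → CP
with permutation significance on eligible sites → time-courses, lagged
matrix, rSC_τ trend → cluster tests (ambiguous-vs-random rSC traces;
the across-site correlation field between the rSC_τ derivative and the
CP time-course; CP traces split by derivative sign).  Per-site failures
are recorded and the study continues.  Everything is seeded;
re-running a config is bit-identical.

The validation cohort gives the ambiguous cylinder fast + slow shared
gain plus choice coupling and the control conditions the fast gain only
— the hypothesis that a slow, choice-linked signal appears only when the
stimulus is bistable.  Gain strengths (c_fast = 0.85, c_slow = 0.10,
β = 0.08 single-site default) were set from the analytic map so that
fast-only conditions sit near rSC 0.25, the ambiguous condition near
0.4, and site CP near 0.65–0.7.  The cohort used by the end-to-end check
has 40 sites — half with the coupled slow component (at β = 0.12), half
without — with 200 ambiguous and 80 control trials per site.  These
sizes come from a power analysis of the across-site correlation between
the rSC_τ derivative and CP: the derivative's discriminability grows
with β², and the field needs signal r ≈ 0.5 against a pointwise
criterion of r ≈ 0.31 at n = 40.  Five independent cohort seeds
reproduced the full pattern before the configuration was frozen.

## Spike-sorting robustness

`misclassify_spikes` moves round(f·N) uniformly chosen spikes of each
train into the other train per trial (collisions with occupied 1 ms bins
are dropped and counted).  Exchanging counts mechanically inflates the
absolute correlation of *every* condition by ≈ f·(V_su+V_mu)/√(V_su·V_mu)
— at f = 0.1 here about +0.17 — because the swapped spikes appear in
both trains.  The meaningful robustness statement is therefore about the
condition contrast: the ambiguous-vs-random rSC difference moves by only
≈ −0.01 against a contrast of ≈ 0.16, so conclusions driven by
between-condition differences survive moderate sorting errors.

## What the synthetic validation does and does not show

The generator produces conditionally Poisson (slightly sub-Poisson after
binarization) spikes with log-normal shared gains, a binary latent
decision, stationary within-trial statistics (apart from the coupling
window), and exact SU/MU exclusivity.  Real recordings have refractory
structure, burstiness, non-stationary onset transients, waveform-drift
sorting errors, and decision dynamics richer than a fixed ±1 latent.
Passing tests therefore establish that the estimators compute the
intended quantities, that their calibrations and false-positive rates
are correct under a known doubly stochastic ground truth, and that the
pipeline detects the designed correlation-timescale and choice-coupling
structure — not that any particular biological circuit produces such
structure.

## Problem sizes

The test suite and the acceptance script scale simulations to desk
sizes chosen for stable statistics: 1000-trial sessions for the
rCCG/rSC identity and shift-predictor checks, 20 seeds × 250 trials for
timescale separation, 16 sessions × 500 trials per calibration target,
200 null simulations at n_perm = 1000 for the false-positive rates
(n_perm = 10000 remains the analysis default), and the 40-site cohort
above with 100 ms time-course steps.
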