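"""Correlogram arithmetic against loop oracles; shift predictor; rCCG properties."""

import numpy as np
import pytest

from spikecorr import synth
from spikecorr.ccg import (compute_ccg, compute_rccg, rccg_rsc_consistency,
                           _symmetric_cumsum)


def brute_force_ccg(X, Y):
    """Triple-loop evaluation of the correlogram definitions.

    Returns (lags, C_raw, CCG, shift_predictor_normalized) with the raw
    cross-correlation averaged over trials, the triangular + geometric-mean
    normalization, and the PSTH-based shift predictor.
    """
    M, T = X.shape
    lags = np.arange(-(T - 1), T)
    c = np.zeros(lags.size)
    for li, tau in enumerate(lags):
        tot = 0.0
        for i in range(M):
            for t in range(T):
                u = t + tau
                if 0 <= u < T:
                    tot += X[i, t] * Y[i, u]
        c[li] = tot / M
    lam_j = X.sum() / (M * T)
    lam_k = Y.sum() / (M * T)
    theta = T - np.abs(lags)
    ccg = c / (theta * np.sqrt(lam_j * lam_k))
    pj = X.mean(axis=0)
    pk = Y.mean(axis=0)
    s = np.zeros(lags.size)
    for li, tau in enumerate(lags):
        for t in range(T):
            u = t + tau
            if 0 <= u < T:
                s[li] += pj[t] * pk[u]
    c_star = (M * s - c) / (M - 1)
    shift = c_star / (theta * np.sqrt(lam_j * lam_k))
    return lags, c, ccg, shift


class TestTinyTrainOracle:
    def test_machine_precision_against_loop_evaluation(self, rng):
        """Eqs for C, Theta-normalized CCG and the PSTH shift predictor on
        tiny random binary trains, to machine precision."""
        for _ in range(20):
            M = rng.integers(2, 5)
            T = rng.integers(5, 21)
            X = (rng.random((M, T)) < 0.3).astype(float)
            Y = (rng.random((M, T)) < 0.3).astype(float)
            if X.sum() == 0 or Y.sum() == 0:
                continue
            res = compute_ccg(X, Y)
            lags, c, ccg, shift = brute_force_ccg(X, Y)
            np.testing.assert_allclose(res.c_raw, c, atol=1e-12)
            np.testing.assert_allclose(res.ccg, ccg, atol=1e-12)
            np.testing.assert_allclose(res.shift_predictor, shift, atol=1e-12)
            np.testing.assert_allclose(res.ccg_corrected, ccg - shift, atol=1e-12)

    def test_hand_worked_two_trial_example(self):
        """10 ms trains with spikes placed by hand; C at a few lags checked
        against direct counting."""
        X = np.zeros((2, 10)); Y = np.zeros((2, 10))
        X[0, [2, 5]] = 1; Y[0, [3, 7]] = 1
        X[1, [4]] = 1;    Y[1, [5, 8]] = 1
        res = compute_ccg(X, Y)
        c0 = res.c_raw[res.T - 1]          # lag 0: no coincidences
        c1 = res.c_raw[res.T]              # lag +1: (2,3) and (4,5) -> 2 pairs / 2 trials
        assert c0 == pytest.approx(0.0)
        assert c1 == pytest.approx(1.0)
        c2 = res.c_raw[res.T + 1]          # lag +2: (5,7) -> 1 pair / 2 trials
        assert c2 == pytest.approx(0.5)

    def test_single_trial_rejected(self):
        X = np.ones((1, 10))
        with pytest.raises(ValueError, match="2 trials"):
            compute_ccg(X, X)

    def test_silent_unit_rejected(self):
        X = np.ones((3, 10)); Y = np.zeros((3, 10))
        with pytest.raises(ValueError):
            compute_ccg(X, Y)


class TestSymmetries:
    def test_unit_swap_negates_lags(self, rng):
        X = (rng.random((4, 30)) < 0.2).astype(float)
        Y = (rng.random((4, 30)) < 0.2).astype(float)
        ab = compute_ccg(X, Y)
        ba = compute_ccg(Y, X)
        np.testing.assert_allclose(ab.ccg, ba.ccg[::-1], atol=1e-12)

    def test_poisson_acg_peak_near_one(self, independent_session):
        """ACG(0) of a Poisson train normalized to spikes-per-bin is 1; the
        flat-PSTH shift predictor removes its own lambda at lag 0."""
        sess, _ = independent_session
        idx = np.arange(200)
        res = compute_ccg(sess.binary_trains("SU", idx),
                          sess.binary_trains("MU", idx))
        assert res.acg_j[res.T - 1] == pytest.approx(1.0 - res.rate_j, abs=0.02)
        assert res.acg_k[res.T - 1] == pytest.approx(1.0 - res.rate_k, abs=0.02)

    def test_symmetric_cumsum_matches_loop(self, rng):
        T = 15
        v = rng.normal(size=2 * T - 1)
        got = _symmetric_cumsum(v, T)
        for t in range(T):
            expected = v[T - 1 - t:T + t].sum()
            assert got[t] == pytest.approx(expected, abs=1e-12)


class TestShiftPredictor:
    def test_removes_stimulus_locked_correlation(self, rng):
        """Independent trains sharing a strong ramping PSTH: the raw CCG is
        dominated by stimulus locking, the corrected CCG is flat near 0."""
        M, T = 400, 500
        ramp = np.linspace(10, 50, T) / 1000.0   # 10 -> 50 spikes/s
        X = (rng.random((M, T)) < ramp).astype(float)
        Y = (rng.random((M, T)) < ramp).astype(float)
        res = compute_ccg(X, Y)
        # raw correlogram carries the stimulus-locked structure ...
        assert res.ccg[res.T - 1] > 0.02
        # ... which the shift predictor removes by two orders of magnitude
        assert abs(res.ccg_corrected[res.T - 1]) < 0.1 * res.ccg[res.T - 1]
        curve = compute_rccg(res)
        assert abs(curve.value_full) < 3.0 / np.sqrt(M)   # count corr of independent trains

    def test_trial_shuffle_oracle(self, rng):
        """The PSTH form of the shift predictor equals the average over all
        cross-trial pairings, evaluated by explicit shuffling."""
        M, T = 5, 12
        X = (rng.random((M, T)) < 0.3).astype(float)
        Y = (rng.random((M, T)) < 0.3).astype(float)
        if X.sum() == 0 or Y.sum() == 0:
            pytest.skip("degenerate draw")
        res = compute_ccg(X, Y)
        lags = np.arange(-(T - 1), T)
        shuf = np.zeros(lags.size)
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                for li, tau in enumerate(lags):
                    for t in range(T):
                        u = t + tau
                        if 0 <= u < T:
                            shuf[li] += X[i, t] * Y[j, u]
        shuf /= M * (M - 1)
        lam = np.sqrt(res.rate_j * res.rate_k)
        np.testing.assert_allclose(res.shift_predictor,
                                   shuf / ((T - np.abs(lags)) * lam), atol=1e-12)


class TestRccg:
    def test_independent_trains_full_integral_equals_count_correlation(
            self, independent_session):
        sess, _ = independent_session
        idx = np.arange(300)
        res = compute_ccg(sess.binary_trains("SU", idx),
                          sess.binary_trains("MU", idx))
        curve = compute_rccg(res)
        # exclusivity makes small-tau values negative; full integral is the
        # (slightly negative) count correlation, exactly
        assert curve.rccg[0] < 0
        plain = np.corrcoef(sess.spike_counts("SU", idx),
                            sess.spike_counts("MU", idx))[0, 1]
        assert curve.value_full == pytest.approx(plain, abs=1e-9)

    def test_exclusive_pair_starts_below_zero(self, ambiguous_session):
        sess, _ = ambiguous_session
        idx = sess.trial_indices(("cylinder", 0.0))
        res = compute_ccg(sess.binary_trains("SU", idx),
                          sess.binary_trains("MU", idx))
        assert res.c_raw[res.T - 1] == pytest.approx(0.0, abs=1e-9)  # no lag-0 coincidences
        curve = compute_rccg(res)
        assert curve.rccg[0] < 0
        assert curve.value_full > 0.15        # but full integral recovers the rSC

    def test_slow_gain_keeps_rising_fast_gain_plateaus(self):
        fast_cfg = synth.GeneratorConfig(
            conditions=(synth.Condition("random_motion"),),
            n_trials_per_condition=300, c_fast=0.85, seed=31)
        slow_cfg = synth.GeneratorConfig(
            conditions=(synth.Condition("random_motion"),),
            n_trials_per_condition=300, c_fast=0.85, c_slow=0.12,
            tau_slow_ms=300.0, seed=31)
        diffs = {}
        for name, cfg in (("fast", fast_cfg), ("slow", slow_cfg)):
            sess, _ = synth.generate_session(cfg)
            idx = sess.trial_indices(("random_motion", None))
            res = compute_ccg(sess.binary_trains("SU", idx),
                              sess.binary_trains("MU", idx))
            curve = compute_rccg(res)
            diffs[name] = curve.value_at_400 - curve.value_at_40
        assert diffs["slow"] > diffs["fast"] + 0.05

    def test_rccg_full_equals_count_correlation_at_any_rate(self):
        """The shift-corrected raw cross-correlation summed over all lags
        is (M-1) times the sample count covariance, and the ACG sums are
        the variances — so rCCG at full lag IS the Pearson correlation of
        the spike counts, exactly, whatever the firing rates (the count
        correlation itself is rate-dependent in a doubly stochastic
        model, so only this identity is invariant)."""
        for scale in (1.0, 2.0):
            cfg = synth.GeneratorConfig(
                conditions=(synth.Condition("random_motion"),),
                n_trials_per_condition=400, base_rate_su=30 * scale,
                base_rate_mu=60 * scale, c_slow=0.15, seed=5)
            sess, _ = synth.generate_session(cfg)
            idx = sess.trial_indices(("random_motion", None))
            res = compute_ccg(sess.binary_trains("SU", idx),
                              sess.binary_trains("MU", idx))
            full = compute_rccg(res).value_full
            plain = np.corrcoef(sess.spike_counts("SU", idx),
                                sess.spike_counts("MU", idx))[0, 1]
            assert full == pytest.approx(plain, abs=1e-9)


def test_consistency_report_structure():
    rep = rccg_rsc_consistency(0.31, 0.29)
    assert rep["difference"] == pytest.approx(0.02)
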