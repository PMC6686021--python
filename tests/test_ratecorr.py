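"""Detrended rSC, outlier removal, time-courses, lagged matrices, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecorr import ratecorr
from spikecorr.ratecorr import (LaggedCorrelationMatrix, compute_rsc, fisher_z,
                                fit_trend, remove_outlier_trials, rsc_matrix,
                                rsc_tau, rsc_timecourse,
                                sliding_window_counts, zscore_sliding)


def _brute_force_zscore(counts, half=5):
    """Direct loop evaluation of the sliding-trial z-score definition."""
    counts = np.asarray(counts, float)
    n = counts.size
    z = np.zeros(n)
    for k in range(n):
        nb = np.concatenate([counts[max(0, k - half):k], counts[k + 1:k + 1 + half]])
        mu = nb.mean()
        sd = nb.std(ddof=1) if nb.size > 1 else 0.0
        z[k] = (counts[k] - mu) / sd if sd > 0 else 0.0
    return z


class TestOutlierRemoval:
    def test_equal_counts_remove_nothing(self):
        keep = remove_outlier_trials(np.full(10, 20.0), np.full(10, 30.0))
        assert keep.tolist() == list(range(10))

    def test_single_extreme_trial_removed(self):
        su = np.full(20, 30.0) + np.arange(20) % 3   # some spread
        mu = su.copy()
        su[7] = su.mean() + 10 * su.std(ddof=1)
        keep = remove_outlier_trials(su, mu)
        assert 7 not in keep

    def test_matches_brute_force_rule(self, rng):
        su = rng.poisson(40, 50).astype(float)
        mu = rng.poisson(70, 50).astype(float)
        su[3] += 60; mu[11] += 90
        keep = remove_outlier_trials(su, mu)
        expected = [i for i in range(50)
                    if abs(su[i] - su.mean()) <= 3 * su.std(ddof=1)
                    and abs(mu[i] - mu.mean()) <= 3 * mu.std(ddof=1)]
        assert keep.tolist() == expected

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            remove_outlier_trials([1, 2, 3], [1, 2, 3])


class TestSlidingZScore:
    def test_hand_worked_example(self):
        """Trial with neighbours {8,10,12,10,10, 10,10,10,10,10} and own
        count 12: z = (12 - mu) / sd over exactly those ten values."""
        seq = np.array([8, 10, 12, 10, 10, 12, 10, 10, 10, 10, 10], float)
        nb = np.concatenate([seq[:5], seq[6:]])
        expected = (12 - nb.mean()) / nb.std(ddof=1)
        res = zscore_sliding(seq)
        assert res.z[5] == pytest.approx(expected)

    def test_constant_sequence_gives_zero(self):
        res = zscore_sliding(np.full(30, 17.0))
        np.testing.assert_array_equal(res.z, 0.0)
        assert not res.unreliable.any()

    def test_matches_brute_force_including_edges(self, rng):
        counts = rng.poisson(35, 40).astype(float)
        res = zscore_sliding(counts)
        np.testing.assert_allclose(res.z, _brute_force_zscore(counts), atol=1e-10)

    def test_linear_drift_removed(self):
        """A pure linear trend in counts leaves no trend in the interior
        z-scores (edge trials have asymmetric windows and keep a residue)."""
        counts = 20.0 + 0.8 * np.arange(60)
        z = zscore_sliding(counts).z
        np.testing.assert_allclose(z[5:-5], z[5], atol=1e-9)   # constant interior
        slope = np.polyfit(np.arange(50), z[5:-5], 1)[0]
        assert abs(slope) < 1e-9
        np.testing.assert_allclose(z, _brute_force_zscore(counts), atol=1e-10)

    def test_matrix_form_matches_vector_form(self, rng):
        X = rng.poisson(30, size=(25, 7)).astype(float)
        zmat, *_ = ratecorr.zscore_sliding_matrix(X)
        for j in range(7):
            np.testing.assert_allclose(zmat[:, j], zscore_sliding(X[:, j]).z,
                                       atol=1e-10)


class TestComputeRsc:
    def test_identical_vectors_give_one(self):
        z = np.array([1.0, -0.5, 0.3, 2.0, -1.1])
        assert compute_rsc(z, z).r_sc == pytest.approx(1.0)

    def test_negated_vectors_give_minus_one(self):
        z = np.array([1.0, -0.5, 0.3, 2.0, -1.1])
        assert compute_rsc(z, -z).r_sc == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        res = compute_rsc(np.zeros(10), np.arange(10.0))
        assert not res.valid and np.isnan(res.r_sc)

    def test_fisher_z_odd_and_monotone(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3))
        r = np.linspace(-0.9, 0.9, 19)
        assert np.all(np.diff(fisher_z(r)) > 0)

    @given(st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_rsc_invariant_under_common_affine_transform(self, a, b):
        rng = np.random.default_rng(99)
        su = rng.poisson(40, 40).astype(float)
        mu = su + rng.poisson(10, 40)
        r1 = compute_rsc(zscore_sliding(su), zscore_sliding(mu)).r_sc
        r2 = compute_rsc(zscore_sliding(a * su + b), zscore_sliding(a * mu + b)).r_sc
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestTimecourse:
    def test_full_trial_window_equals_whole_trial_rsc(self, ambiguous_session):
        sess, _ = ambiguous_session
        idx = sess.trial_indices(("cylinder", 0.0))
        centers, r, _ = rsc_timecourse(sess, idx, window_ms=2000.0, step_ms=2000.0)
        assert centers.size == 1
        su = sess.spike_counts("SU", idx)
        mu = sess.spike_counts("MU", idx)
        whole = compute_rsc(zscore_sliding(su), zscore_sliding(mu)).r_sc
        assert r[0] == pytest.approx(whole, abs=1e-12)

    def test_coupling_window_elevates_local_rsc(self):
        """Shared choice signal confined to [800, 2000] ms raises the
        time-resolved correlation there relative to the early trial."""
        from spikecorr import synth
        cfg = synth.GeneratorConfig(
            conditions=(synth.Condition("cylinder", 0.0),),
            n_trials_per_condition=400, c_fast=0.0, c_slow=0.0,
            choice_coupling=0.25, coupling_onset_ms=800,
            coupling_offset_ms=2000, seed=17)
        sess, _ = synth.generate_session(cfg)
        idx = sess.trial_indices(("cylinder", 0.0))
        centers, r, _ = rsc_timecourse(sess, idx, window_ms=100.0, step_ms=50.0)
        inside = r[(centers > 900) & (centers < 1900)].mean()
        outside = r[centers < 700].mean()
        assert inside > outside + 0.05

    def test_sliding_counts_match_direct_histogram(self, independent_session):
        sess, _ = independent_session
        idx = np.arange(10)
        counts, centers = sliding_window_counts(sess, idx, "SU", 100.0, 250.0)
        for j, c in enumerate(centers):
            direct = sess.spike_counts("SU", idx, window_ms=(c - 50, c + 50))
            np.testing.assert_array_equal(counts[:, j], direct)


class TestLaggedMatrix:
    def test_diagonal_equals_binned_rsc_sequence(self, ambiguous_session):
        sess, _ = ambiguous_session
        idx = sess.trial_indices(("cylinder", 0.0))
        lag = rsc_matrix(sess, idx, bin_ms=100.0)
        assert lag.matrix.shape == (20, 20)
        edges = np.arange(0.0, 2000.1, 100.0)
        su = sess.binned_counts("SU", idx, edges)
        mu = sess.binned_counts("MU", idx, edges)
        for i in range(20):
            direct = compute_rsc(zscore_sliding(su[:, i]),
                                 zscore_sliding(mu[:, i])).r_sc
            assert lag.matrix[i, i] == pytest.approx(direct, abs=1e-10)
        np.testing.assert_allclose(lag.diagonal, rsc_tau(lag, 0), atol=1e-12)

    def test_rsc_tau_edge_clipped_hand_example(self):
        M = np.arange(16, dtype=float).reshape(4, 4)
        lag = LaggedCorrelationMatrix(matrix=M, bin_centers_ms=np.arange(4.0),
                                      bin_ms=1.0, n_trials=10)
        got = rsc_tau(lag, tau=1)
        # bin 0: entries M[0,1], M[1,0] only (left edge clipped)
        assert got[0] == pytest.approx((M[0, 1] + M[1, 0]) / 2)
        # bin 1: M[1,2], M[2,1], M[1,0], M[0,1]
        assert got[1] == pytest.approx((M[1, 2] + M[2, 1] + M[1, 0] + M[0, 1]) / 4)

    def test_fast_only_correlation_stays_on_diagonal(self):
        """A 10 ms shared gain correlates same-bin counts but not bins
        hundreds of milliseconds apart."""
        from spikecorr import synth
        cfg = synth.GeneratorConfig(
            conditions=(synth.Condition("random_motion"),),
            n_trials_per_condition=600, c_fast=0.85, seed=29)
        sess, _ = synth.generate_session(cfg)
        lag = rsc_matrix(sess, sess.trial_indices(("random_motion", None)))
        diag = np.nanmean(np.diag(lag.matrix))
        off = lag.matrix[np.abs(np.subtract.outer(range(20), range(20))) >= 3]
        assert diag > 0.1
        assert abs(np.nanmean(off)) < 0.03


class TestTrendFit:
    def test_linear_input_gives_constant_derivative(self):
        t = np.arange(50.0, 2000.0, 100.0)
        fit = fit_trend(0.001 * t + 0.2, t)
        np.testing.assert_allclose(fit.derivative, 0.001, atol=1e-9)
        assert fit.mean_derivative == pytest.approx(0.001, abs=1e-9)

    def test_symmetric_bump_has_zero_crossing_at_peak(self):
        t = np.arange(50.0, 2000.0, 100.0)
        values = -((t - 800.0) ** 2) * 1e-7 + 0.3
        fit = fit_trend(values, t)
        crossing = -fit.coefficients[1] / (2 * fit.coefficients[0])
        assert crossing == pytest.approx(800.0, abs=1.0)

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(50.0, 2000.0, 100.0)
        y = rng.normal(0.2, 0.05, t.size)
        fit = fit_trend(y, t)
        X = np.column_stack([t ** 2, t, np.ones_like(t)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta, rtol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([0.1, np.nan, 0.2], np.array([0.0, 1.0, 2.0]))
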