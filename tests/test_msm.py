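"""Microstate clustering, transition matrices, timescales, PCCA+, TPT."""

import numpy as np
import pytest

from conformscape import msm, synth
from conformscape.errors import ValidationError
from conformscape.msm import (choose_lag, cluster_microstates, estimate_tpm,
                              implied_timescales, mfpt, pcca_macrostates,
                              representative_frame, timescale_from_eigenvalue)


class TestClusterMicrostates:
    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal([50, 100], [0.3, 2], size=(40, 2))
        b = rng.normal([58, 240], [0.3, 2], size=(40, 2))
        model = cluster_microstates([np.vstack([a, b])], k=2, seed=1,
                                    auto_scale=False)
        labels = model.assignments[0]
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        model = cluster_microstates([X], k=1, seed=0, auto_scale=False)
        assert (model.assignments[0] == 0).all()
        # center is stored in z-space: the data mean maps to the origin
        assert np.allclose(model.centers[0], 0.0, atol=1e-12)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        m1 = cluster_microstates([X], k=10, seed=5, auto_scale=False)
        m2 = cluster_microstates([X], k=10, seed=5, auto_scale=False)
        assert np.array_equal(m1.assignments[0], m2.assignments[0])

    def test_too_few_frames_guidance(self):
        with pytest.raises(ValidationError, match="reduce k"):
            cluster_microstates([np.zeros((5, 2))], k=10, auto_scale=False)

    def test_auto_scale_caps_k(self):
        rng = np.random.default_rng(3)
        model = cluster_microstates([rng.normal(size=(100, 2))], k=500, seed=0)
        assert model.k <= 10


class TestEstimateTPM:
    def test_naive_counting_example(self):
        m = estimate_tpm([[0, 1, 0, 1]], lag=1, mode="naive")
        assert np.array_equal(m.counts, [[0, 2], [1, 0]])
        assert np.array_equal(m.transition_matrix, [[0, 1], [1, 0]])

    def test_symmetric_chain_stationary_is_uniform(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = synth.simulate_chain(T, steps=20_000, seed=4)
        m = estimate_tpm([seq], lag=1)
        assert np.allclose(m.stationary, [0.5, 0.5], atol=0.02)

    def test_three_state_chain_concentrates(self):
        T = np.array([[0.90, 0.08, 0.02],
                      [0.05, 0.90, 0.05],
                      [0.02, 0.08, 0.90]])
        seq = synth.simulate_chain(T, steps=100_000, seed=7)
        m = estimate_tpm([seq], lag=1, mode="naive")
        assert np.abs(m.transition_matrix - T).max() < 0.01

    def test_row_stochastic_and_fixed_point(self, microstates_small):
        m = estimate_tpm(microstates_small.assignments, lag=2)
        assert np.allclose(m.transition_matrix.sum(axis=1), 1.0, atol=1e-12)
        assert m.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(m.stationary @ m.transition_matrix, m.stationary,
                           atol=1e-10)
        assert m.stationary.min() >= 0
        assert m.stationary.sum() == pytest.approx(1.0)

    def test_detailed_balance_in_symmetrized_mode(self, microstates_small):
        m = estimate_tpm(microstates_small.assignments, lag=2)
        flux = m.stationary[:, None] * m.transition_matrix
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_no_transitions_across_trajectory_boundaries(self):
        # two constant trajectories in different states: no cross counts
        m = estimate_tpm([[0] * 10, [1] * 10], lag=1, mode="naive")
        # disconnected graph → restricted to the heavier component
        assert m.n_states == 1

    def test_disconnected_warns(self):
        with pytest.warns(UserWarning, match="strongly connected"):
            estimate_tpm([[0] * 10 + [1] * 5], lag=1, mode="naive")

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValidationError, match="lag"):
            estimate_tpm([[0, 1]], lag=5)


class TestImpliedTimescales:
    def test_closed_form_identities(self):
        assert timescale_from_eigenvalue(np.exp(-1.0), 4.0) == pytest.approx(4.0)
        assert timescale_from_eigenvalue(0.5, 4.0) == pytest.approx(
            4.0 / np.log(2), abs=1e-12)
        assert timescale_from_eigenvalue(1.0, 4.0) == np.inf
        assert np.isnan(timescale_from_eigenvalue(-0.2, 4.0))

    def test_sampled_chain_matches_analytic(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        lam2 = 0.9
        analytic = -1.0 / np.log(lam2)
        seq = synth.simulate_chain(T, steps=100_000, seed=11)
        scan = implied_timescales([seq], lags=[1, 2, 3, 5], n_timescales=1)
        assert np.allclose(scan.timescales[:, 0], analytic, rtol=0.10)

    def test_markovian_chain_flat_across_lags(self):
        T = np.array([[0.92, 0.05, 0.03],
                      [0.04, 0.92, 0.04],
                      [0.03, 0.05, 0.92]])
        seq = synth.simulate_chain(T, steps=100_000, seed=13)
        scan = implied_timescales([seq], lags=list(range(1, 11)),
                                  n_timescales=1)
        t2 = scan.timescales[:, 0]
        assert (t2.max() - t2.min()) / t2.min() < 0.10

    def test_timescales_decreasing_within_lag(self, microstates_small):
        scan = implied_timescales(microstates_small.assignments, [2, 4],
                                  n_timescales=3)
        for row in scan.timescales:
            finite = row[np.isfinite(row)]
            assert (np.diff(finite) <= 1e-9).all()


class TestChooseLag:
    def _scan(self, slowest):
        n = len(slowest)
        return msm.ImpliedTimescaleScan(
            lags=np.arange(1, n + 1), lag_times=np.arange(1.0, n + 1),
            timescales=np.column_stack([np.asarray(slowest, float)]))

    def test_flat_scan_picks_smallest(self):
        choice = choose_lag(self._scan([14.0, 14.1, 14.05, 14.02]))
        assert choice.lag_frames == 1 and choice.markovian

    def test_rule_arithmetic_example(self):
        choice = choose_lag(self._scan([10, 14, 14.5, 14.6, 14.7]))
        assert choice.lag_frames == 2 and choice.markovian

    def test_monotone_rise_flagged_non_markovian(self):
        choice = choose_lag(self._scan([10, 12, 15, 19, 24]))
        assert not choice.markovian
        assert choice.lag_frames == 5


class TestPCCA:
    def test_block_chain_recovered_exactly(self):
        eps = 0.01
        T = np.array([
            [0.95 - eps, 0.05, eps, 0.0],
            [0.05, 0.95 - eps, 0.0, eps],
            [eps, 0.0, 0.95 - eps, 0.05],
            [0.0, eps, 0.05, 0.95 - eps],
        ])
        seq = synth.simulate_chain(T, steps=200_000, seed=17)
        model = estimate_tpm([seq], lag=1)
        macro = pcca_macrostates(model, n_macro=2)
        g = macro.micro_to_macro
        assert g[0] == g[1] and g[2] == g[3] and g[0] != g[2]

    def test_identity_lumping(self):
        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        seq = synth.simulate_chain(T, steps=50_000, seed=19)
        model = estimate_tpm([seq], lag=1)
        macro = pcca_macrostates(model, n_macro=model.n_states)
        assert sorted(macro.micro_to_macro.tolist()) == [0, 1]

    def test_proportions_sum_to_one_nonempty(self, microstates_small):
        model = estimate_tpm(microstates_small.assignments, lag=2)
        macro = pcca_macrostates(model, n_macro=3)
        assert macro.proportions.sum() == pytest.approx(1.0)
        assert all((macro.micro_to_macro == m).any() for m in range(3))

    def test_no_spectral_gap_warns(self):
        # 4-state ring: eigenvalues come in a degenerate pair
        T = np.array([[0.9, 0.05, 0.0, 0.05],
                      [0.05, 0.9, 0.05, 0.0],
                      [0.0, 0.05, 0.9, 0.05],
                      [0.05, 0.0, 0.05, 0.9]])
        seq = synth.simulate_chain(T, steps=3_000, seed=23)
        model = estimate_tpm([seq], lag=1)
        lam = np.sort(np.real(model.eigenvalues))[::-1]
        if abs(lam[1] - lam[2]) < 1e-6:
            with pytest.warns(UserWarning, match="spectral gap"):
                pcca_macrostates(model, n_macro=2)


class TestTPT:
    def _two_state(self, p=0.1, dt=1.0):
        T = np.array([[1 - p, p], [p, 1 - p]])
        return msm.TransitionModel(
            lag_frames=1, lag_time=dt, counts=T, transition_matrix=T,
            eigenvalues=np.array([1.0, 1 - 2 * p]),
            stationary=np.array([0.5, 0.5]), states=np.arange(2))

    def test_two_state_geometric_mfpt(self):
        res = mfpt(self._two_state(p=0.1, dt=0.5), [0], [1])
        assert res.mfpt == pytest.approx(10 * 0.5)

    def test_committor_boundary_conditions(self):
        res = mfpt(self._two_state(), [0], [1])
        assert res.committor[0] == 0.0
        assert res.committor[1] == 1.0

    def test_birth_death_matches_dense_oracle(self):
        T = np.array([[0.7, 0.3, 0.0],
                      [0.2, 0.5, 0.3],
                      [0.0, 0.4, 0.6]])
        pi = np.real(np.linalg.eig(T.T)[1][:, 0])
        pi = np.abs(pi) / np.abs(pi).sum()
        model = msm.TransitionModel(
            lag_frames=1, lag_time=1.0, counts=T, transition_matrix=T,
            eigenvalues=np.sort(np.linalg.eigvals(T))[::-1],
            stationary=pi, states=np.arange(3))
        res = mfpt(model, [0], [2])
        # oracle: solve (I - T_{AA}) t = 1 on non-sink states directly
        A = np.eye(2) - T[:2, :2]
        t = np.linalg.solve(A, np.ones(2))
        assert res.mfpt == pytest.approx(t[0], abs=1e-8)

    def test_matches_empirical_hitting_time(self):
        T = np.array([[0.90, 0.08, 0.02],
                      [0.10, 0.80, 0.10],
                      [0.05, 0.15, 0.80]])
        pi = np.real(np.linalg.eig(T.T)[1][:, 0])
        pi = np.abs(pi) / np.abs(pi).sum()
        model = msm.TransitionModel(
            lag_frames=1, lag_time=1.0, counts=T, transition_matrix=T,
            eigenvalues=np.sort(np.real(np.linalg.eigvals(T)))[::-1],
            stationary=pi, states=np.arange(3))
        res = mfpt(model, [0], [2])
        rng = np.random.default_rng(29)
        cum = np.cumsum(T, axis=1)
        total_steps = 0
        times = []
        while total_steps < 1_000_000:
            s, t = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], rng.random()))
                t += 1
            times.append(t)
            total_steps += t
        assert res.mfpt == pytest.approx(np.mean(times), rel=0.05)

    def test_unreachable_sink_infinite(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        model = msm.TransitionModel(
            lag_frames=1, lag_time=1.0, counts=T, transition_matrix=T,
            eigenvalues=np.array([1.0, 0.5]),
            stationary=np.array([1.0, 0.0]), states=np.arange(2))
        res = mfpt(model, [1], [0])  # fine: reachable
        assert np.isfinite(res.mfpt)
        res = mfpt(model, [0], [1])  # state 0 absorbing: sink unreachable
        assert np.isinf(res.mfpt)

    def test_source_sink_must_be_disjoint(self):
        with pytest.raises(ValidationError):
            mfpt(self._two_state(), [0], [0])


class TestRepresentativeFrame:
    def test_identical_frames_tie_break(self):
        assert representative_frame(np.zeros((4, 4))) == 0

    def test_three_frame_hand_example(self):
        d = np.array([[0.0, 1.0, 1.0],
                      [1.0, 0.0, 4.0],
                      [1.0, 4.0, 0.0]])
        assert representative_frame(d) == 0

    def test_outlier_never_wins(self):
        d = np.full((5, 5), 0.1)
        np.fill_diagonal(d, 0.0)
        d[4, :4] = d[:4, 4] = 50.0
        assert representative_frame(d) in (0, 1, 2, 3)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            representative_frame(d)
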