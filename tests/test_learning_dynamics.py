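"""The coupled forward/inverse learning dynamics."""

import numpy as np
import pytest

from bomilearn import (
    DivergenceError,
    InterfaceMap,
    LearnerParams,
    LearnerState,
    ProtocolConfig,
    forward_model_error,
    generate_targets,
    plan_action,
    run_session,
    run_two_phase,
    step_trial,
    update_forward,
    update_inverse,
)
from conftest import random_orthonormal_map


def brute_force_forward(H_hat, q, p, eps):
    """Element-wise oracle for the forward update."""
    K, S = H_hat.shape
    out = np.empty_like(H_hat)
    for i in range(K):
        pred_i = sum(H_hat[i, j] * q[j] for j in range(S))
        for j in range(S):
            out[i, j] = H_hat[i, j] + eps * (p[i] - pred_i) * q[j]
    return out


def brute_force_inverse(G, H_hat, e, u, eta):
    S, K = G.shape
    out = np.empty_like(G)
    for j in range(S):
        he_j = sum(H_hat[i, j] * e[i] for i in range(K))
        for k in range(K):
            out[j, k] = G[j, k] - eta * he_j * u[k]
    return out


def numeric_gradient(loss, X, h=1e-6):
    g = np.zeros_like(X)
    for idx in np.ndindex(X.shape):
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        g[idx] = (loss(Xp) - loss(Xm)) / (2 * h)
    return g


class TestPlanAction:
    def test_noiseless_action_is_inverse_model_output(self, rng, unit_map):
        state = LearnerState(H_hat=np.zeros((2, 8)), G=rng.standard_normal((8, 2)))
        params = LearnerParams(eta=0.01, epsilon=0.1, sigma=0.0)
        u = np.array([3.0, -4.0])
        q, xi = plan_action(state, u, params, rng)
        assert np.allclose(q, state.G @ u)
        assert np.allclose(xi, 0.0)
        q0, _ = plan_action(state, np.zeros(2), params, rng)
        assert np.allclose(q0, 0.0)

    def test_noise_scale_matches_sigma(self):
        rng = np.random.default_rng(0)
        state = LearnerState(H_hat=np.zeros((2, 8)), G=np.zeros((8, 2)))
        params = LearnerParams(eta=0.0, epsilon=0.0, sigma=0.8)
        draws = np.array(
            [plan_action(state, np.zeros(2), params, rng)[0] for _ in range(10_000)]
        )
        assert np.allclose(draws.std(axis=0), 0.8, rtol=0.03)


class TestUpdateOracles:
    def test_forward_toy_example(self):
        out = update_forward(
            np.zeros((2, 2)), np.array([1.0, 0.0]), np.array([2.0, 0.0]), 0.1
        )
        assert np.allclose(out, [[0.2, 0.0], [0.0, 0.0]])

    def test_forward_fixed_point_at_true_map(self, rng, unit_map):
        q = rng.standard_normal(8)
        p = unit_map.H @ q
        assert np.allclose(update_forward(unit_map.H, q, p, 0.3), unit_map.H)

    def test_inverse_toy_example(self):
        out = update_inverse(
            np.zeros((2, 2)),
            np.eye(2),
            np.array([-1.0, 0.0]),
            np.array([1.0, 0.0]),
            0.5,
        )
        assert np.allclose(out, [[0.5, 0.0], [0.0, 0.0]])

    def test_inverse_no_change_on_zero_error(self, rng):
        G = rng.standard_normal((5, 2))
        out = update_inverse(G, rng.standard_normal((2, 5)), np.zeros(2), np.ones(2), 0.7)
        assert np.allclose(out, G)

    @pytest.mark.parametrize("trial", range(20))
    def test_updates_match_brute_force_and_finite_differences(self, trial):
        rng = np.random.default_rng(trial)
        K, S = rng.integers(1, 4), rng.integers(2, 6)
        if K >= S:
            K = S - 1
        H = rng.standard_normal((K, S))
        H_hat = rng.standard_normal((K, S))
        G = rng.standard_normal((S, K))
        q = rng.standard_normal(S)
        u = rng.standard_normal(K)
        p = H @ q
        eps, eta = rng.uniform(0.01, 0.5, 2)
        fwd = update_forward(H_hat, q, p, eps)
        assert np.allclose(fwd, brute_force_forward(H_hat, q, p, eps), atol=1e-12)
        # gradient of 1/2 |p - H_hat q|^2 via central differences
        g_num = numeric_gradient(
            lambda X: 0.5 * np.sum((p - X @ q) ** 2), H_hat
        )
        assert np.allclose(fwd, H_hat - eps * g_num, atol=1e-6)
        e = (H @ G - np.eye(K)) @ u
        inv = update_inverse(G, H, e, u, eta)
        assert np.allclose(inv, brute_force_inverse(G, H, e, u, eta), atol=1e-12)
        # gradient of 1/2 |(H G - I) u|^2 via central differences
        g_num = numeric_gradient(
            lambda X: 0.5 * np.sum(((H @ X - np.eye(K)) @ u) ** 2), G
        )
        assert np.allclose(inv, G - eta * g_num, atol=1e-6)

    def test_non_finite_inputs_rejected(self):
        bad = np.array([[np.nan, 0.0]])
        with pytest.raises(ValueError):
            update_forward(bad, np.zeros(2), np.zeros(1), 0.1)
        with pytest.raises(ValueError):
            update_inverse(np.zeros((2, 1)), bad, np.array([np.inf]), np.zeros(1), 0.1)


class TestStepTrial:
    def test_converged_state_is_stationary(self, rng, unit_map):
        G = np.linalg.pinv(unit_map.H)
        state = LearnerState(H_hat=unit_map.H, G=G)
        params = LearnerParams(eta=0.1, epsilon=0.1, sigma=0.0)
        new, rec = step_trial(state, unit_map, np.array([1.0, 0.0]), params, rng)
        assert np.allclose(rec.e, 0.0, atol=1e-12)
        assert np.allclose(new.H_hat, state.H_hat)
        assert np.allclose(new.G, state.G)

    def test_record_identities(self, rng, unit_map):
        state = LearnerState(H_hat=np.zeros((2, 8)), G=0.1 * rng.standard_normal((8, 2)))
        params = LearnerParams(eta=0.02, epsilon=0.2, sigma=0.5)
        u = np.array([5.0, 0.0])
        _, rec = step_trial(state, unit_map, u, params, rng)
        assert np.allclose(rec.e, rec.p - u)
        assert np.allclose(rec.p, unit_map.H @ rec.q + unit_map.origin)
        assert np.allclose(rec.q, state.G @ u + rec.xi)
        assert np.allclose(rec.p_pred, state.H_hat @ rec.q)

    def test_same_seed_reproduces_trials(self, unit_map):
        params = LearnerParams(eta=0.02, epsilon=0.2, sigma=0.7, seed=11)
        seq = generate_targets(ProtocolConfig(seed=1, n_blocks=1))
        a = run_session(unit_map, seq, params)
        b = run_session(unit_map, seq, params)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.q, rb.q)
            assert np.array_equal(ra.e, rb.e)
        assert np.array_equal(a.G_traj, b.G_traj)

    def test_geometric_error_decay_in_analytic_limit(self, rng):
        # Row-orthonormal H with |H| = 1, frozen correct forward model,
        # no noise, repeated unit target: |e_n| = (1 - eta)^n |e_0|.
        imap = random_orthonormal_map(rng, norm=1.0)
        eta = 0.07
        params = LearnerParams(eta=eta, epsilon=0.0, sigma=0.0)
        state = LearnerState(H_hat=imap.H, G=0.3 * rng.standard_normal((8, 2)))
        u = np.array([1.0, 0.0])
        _, rec0 = step_trial(state, imap, u, params, rng)
        e0 = rec0.e
        for n in range(1, 101):
            state, rec = step_trial(state, imap, u, params, rng)
            assert np.allclose(rec.e, (1 - eta) ** (n - 1) * e0, atol=1e-10)


class TestRunSession:
    def test_frozen_learner_keeps_errors_constant(self, rng, unit_map):
        params = LearnerParams(eta=0.0, epsilon=0.0, sigma=0.0, seed=2)
        seq = generate_targets(ProtocolConfig(seed=2, n_blocks=1, reps_per_block=2))
        res = run_session(unit_map, seq, params)
        assert np.allclose(res.G_traj[0], res.G_traj[-1])
        assert np.allclose(res.H_hat_traj[0], res.H_hat_traj[-1])
        errs_by_target = {}
        for rec, tid in zip(res.records, seq.target_id):
            errs_by_target.setdefault(tid, []).append(rec.reaching_error)
        for errs in errs_by_target.values():
            assert np.allclose(errs, errs[0])

    def test_divergence_guard_names_trial(self, rng, unit_map):
        # raw (unsafeguarded) forward update with a large rate diverges
        params = LearnerParams(
            eta=0.3, epsilon=2.5, sigma=1.0, seed=0, forward_step_clip=None
        )
        seq = generate_targets(ProtocolConfig(seed=0))
        with pytest.raises(DivergenceError) as exc:
            run_session(unit_map, seq, params, divergence_factor=1e4)
        assert exc.value.trial >= 0

    def test_plateau_stop_rule_truncates(self, rng):
        imap = random_orthonormal_map(rng, norm=1.0)
        params = LearnerParams(eta=0.04, epsilon=0.0, sigma=0.0)
        init = LearnerState(H_hat=imap.H, G=np.zeros((8, 2)))
        seq = generate_targets(ProtocolConfig(seed=5))
        res = run_session(imap, seq, params, init=init, stop_rule="plateau")
        assert res.stopped_at is not None
        assert len(res) < len(seq)


class TestTwoPhase:
    def test_inverse_model_frozen_during_babbling(self, rng, unit_map):
        params = LearnerParams(eta=0.03, epsilon=0.2, sigma=0.7, seed=4)
        seq = generate_targets(ProtocolConfig(seed=4, n_blocks=1))
        res = run_two_phase(unit_map, seq, params, babble_trials=50)
        for G in res.G_traj[: 50 + 1]:
            assert np.array_equal(G, res.G_traj[0])
        # and the forward estimate is frozen during reaching
        for H in res.H_hat_traj[51:]:
            assert np.array_equal(H, res.H_hat_traj[51])

    def test_babbling_drives_forward_error_down(self, unit_map):
        fmes = []
        for seed in range(5):
            params = LearnerParams(eta=0.0, epsilon=0.2, sigma=0.7, seed=seed)
            res = run_two_phase(unit_map, [], params, babble_trials=200)
            curve = [forward_model_error(unit_map, H) for H in res.H_hat_traj]
            fmes.append(curve)
        med = np.median(fmes, axis=0)
        assert med[-1] < 0.05 * med[0]
        # non-increasing in trend: compare block medians
        blocks = np.array_split(med, 5)
        block_meds = [np.median(b) for b in blocks]
        assert all(a >= b - 1e-9 for a, b in zip(block_meds, block_meds[1:]))
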