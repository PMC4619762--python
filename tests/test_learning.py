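"""Action selection, accessory credit assignment and the weight update."""

import numpy as np
import pytest

import relearnn as rl
from relearnn import learning, oracles
from relearnn.dynamics import firing_rate, firing_rate_deriv

from conftest import random_mixed_net


class TestSoftmax:
    def test_equal_potentials_uniform(self):
        out = rl.select_action_softmax(np.full(5, 0.3), tau=0.1, greedy=True)
        np.testing.assert_allclose(out.probabilities, 0.2)

    def test_two_action_closed_form(self):
        out = rl.select_action_softmax(
            np.array([0.2, 0.4]), tau=0.1, greedy=True
        )
        expect = np.array([1 / (1 + np.e**2), np.e**2 / (1 + np.e**2)])
        np.testing.assert_allclose(out.probabilities, expect, rtol=1e-12)

    def test_probabilities_sum_to_one_and_in_open_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(-0.2, 1.0, rng.integers(2, 8))
            out = rl.select_action_softmax(p, tau=0.05, rng=rng)
            assert out.probabilities.sum() == pytest.approx(1.0)
            assert np.all(out.probabilities > 0)
            assert np.all(out.probabilities < 1)

    def test_temperature_limits(self):
        p = np.array([0.1, 0.5, 0.3])
        cold = rl.select_action_softmax(p, tau=1e-4, greedy=True)
        assert cold.probabilities[1] == pytest.approx(1.0, abs=1e-12)
        hot = rl.select_action_softmax(p, tau=1e4, greedy=True)
        np.testing.assert_allclose(hot.probabilities, 1 / 3, atol=1e-4)

    def test_greedy_breaks_ties_by_lowest_index(self):
        out = rl.select_action_softmax(np.array([0.4, 0.4, 0.1]), 0.1, greedy=True)
        assert out.chosen == 0

    def test_sampling_frequencies_match_probabilities(self):
        """Monte-Carlo check: empirical frequencies within 3 SE of softmax."""
        rng = np.random.default_rng(42)
        p = np.array([0.1, 0.35, 0.5])
        tau = 0.15
        n = 100_000
        phi = rl.select_action_softmax(p, tau, greedy=True).probabilities
        counts = np.zeros(3)
        for _ in range(n):
            counts[rl.select_action_softmax(p, tau, rng=rng).chosen] += 1
        freq = counts / n
        se = np.sqrt(phi * (1 - phi) / n)
        assert np.all(np.abs(freq - phi) < 3 * se + 1e-12)

    def test_numerical_safety_with_large_potentials(self):
        out = rl.select_action_softmax(np.array([1e4, 0.0]), tau=1e-3, greedy=True)
        assert np.isfinite(out.probabilities).all()
        assert out.probabilities[0] == pytest.approx(1.0)


class TestRewardPredictionError:
    @pytest.mark.parametrize(
        "reward,potential,expect",
        [(0.8, 0.8, 0.0), (0.0, 0.3, -0.3), (0.8, 0.1, 0.7)],
    )
    def test_values(self, reward, potential, expect):
        assert rl.reward_prediction_error(reward, potential) == pytest.approx(expect)


def _converged_state(weights, I_inp, prm):
    st = rl.relax_to_fixed_point(weights, I_inp, prm)
    assert st.converged
    return st


class TestLinearization:
    def test_excitatory_chain_matches_hand_formula(self, prm):
        """3-unit excitatory chain: entries equal
        -delta_nm (alpha + I_m) + (beta - p_m) W_nm g'(p_n)."""
        n = 3
        W_ex = np.zeros((n, n))
        W_ex[0, 1] = 0.4
        W_ex[1, 2] = 0.3
        z = np.zeros((n, n))
        W_inp = np.zeros((1, n))
        W_inp[0, 0] = 1.0
        w = rl.WeightSet.from_dense(W_inp, W_ex, z, z)
        st = _converged_state(w, np.array([0.8]), prm)
        adj = rl.linearize_at_fixed_point(st, w, prm, sparse=False)
        p = st.p
        I = st.I_ex
        g = firing_rate_deriv(p, prm.a)
        for m in range(n):
            for nn in range(n):
                expect = (prm.beta - p[m]) * W_ex[nn, m] * g[nn]
                if m == nn:
                    expect -= prm.alpha + I[m]
                assert adj.jacobian[m, nn] == pytest.approx(expect, rel=1e-10)

    def test_zero_recurrent_weights_give_diagonal_jacobian(self, prm):
        z = np.zeros((3, 3))
        w = rl.WeightSet.from_dense(np.eye(3) * 0.5, z, z, z)
        I_inp = np.array([0.4, 0.2, 0.9])
        st = _converged_state(w, I_inp, prm)
        adj = rl.linearize_at_fixed_point(st, w, prm, sparse=False)
        expect = -np.diag(prm.alpha + st.I_ex)
        np.testing.assert_allclose(adj.jacobian, expect, rtol=1e-10)

    def test_matches_finite_difference_jacobian(self, prm):
        """Full Jacobian (with inhibition and modulation) vs central
        differences of the dynamics right-hand side."""
        rng = np.random.default_rng(21)
        weights, I_inp = random_mixed_net(rng, n=6, n_inp=2)
        st = _converged_state(weights, I_inp, prm)
        adj = rl.linearize_at_fixed_point(st, weights, prm, sparse=False)

        def rhs(p):
            I_ex, I_inh, I_mod = rl.compute_inputs(weights, p, I_inp, prm.a)
            return (
                -prm.alpha * p
                + (prm.beta - p) * I_ex * (1 + prm.gamma * I_mod)
                - (prm.zeta + p) * I_inh
            )

        # perturb only units whose potential is safely inside the linear
        # branch of g: central differences across the branch point pick up
        # the O(1/a) jump in g'' and are not a valid reference there
        h = 1e-6
        cols = [j for j in range(6) if st.p[j] > 1e-3]
        assert len(cols) >= 3
        for j in cols:
            e = np.zeros(6)
            e[j] = h
            col = (rhs(st.p + e) - rhs(st.p - e)) / (2 * h)
            np.testing.assert_allclose(adj.jacobian[:, j], col, atol=1e-6)

    def test_sparse_and_dense_agree(self, prm):
        rng = np.random.default_rng(23)
        weights, I_inp = random_mixed_net(rng, n=7, n_inp=3)
        st = _converged_state(weights, I_inp, prm)
        dense = rl.linearize_at_fixed_point(st, weights, prm, sparse=False).jacobian
        sparse = rl.linearize_at_fixed_point(st, weights, prm, sparse=True).jacobian
        np.testing.assert_allclose(sparse.toarray(), dense, rtol=1e-12)


class TestAccessory:
    def test_unit_without_path_to_winner_stays_silent(self, prm):
        # units 0 -> 1 chain; unit 2 disconnected
        n = 3
        W_ex = np.zeros((n, n))
        W_ex[0, 1] = 0.4
        z = np.zeros((n, n))
        W_inp = np.zeros((2, n))
        W_inp[0, 0] = 1.0
        W_inp[1, 2] = 1.0
        w = rl.WeightSet.from_dense(W_inp, W_ex, z, z)
        st = _converged_state(w, np.array([0.6, 0.6]), prm)
        adj = rl.linearize_at_fixed_point(st, w, prm, sparse=False)
        acc = rl.propagate_accessory(adj, winner=1, prm=prm, method="solve")
        assert acc.delta_p[2] == pytest.approx(0.0, abs=1e-12)
        assert acc.delta_p[1] > 0

    def test_feedforward_chain_closed_form(self, prm):
        """input -> hidden -> winner, excitatory only:
        dp_hidden = (beta - p_w) W_hw g'(p_h) / ((alpha + I_h)(alpha + I_w))."""
        n = 2
        W_ex = np.zeros((n, n))
        W_ex[0, 1] = 0.5
        z = np.zeros((n, n))
        W_inp = np.array([[1.0, 0.0]])
        w = rl.WeightSet.from_dense(W_inp, W_ex, z, z)
        st = _converged_state(w, np.array([0.7]), prm)
        adj = rl.linearize_at_fixed_point(st, w, prm, sparse=False)
        acc = rl.propagate_accessory(adj, winner=1, prm=prm, method="solve")
        p, I = st.p, st.I_ex
        expect_h = (
            (prm.beta - p[1])
            * W_ex[0, 1]
            * firing_rate_deriv(p[:1], prm.a)[0]
            / ((prm.alpha + I[0]) * (prm.alpha + I[1]))
        )
        assert acc.delta_p[0] == pytest.approx(expect_h, rel=1e-8)
        assert acc.delta_p[1] == pytest.approx(1 / (prm.alpha + I[1]), rel=1e-8)

    def test_relaxation_agrees_with_direct_solve(self, prm):
        rng = np.random.default_rng(31)
        for _ in range(5):
            weights, I_inp = random_mixed_net(rng, n=8, n_inp=3)
            st = _converged_state(weights, I_inp, prm)
            adj = rl.linearize_at_fixed_point(st, weights, prm, sparse=False)
            direct = rl.propagate_accessory(adj, 7, prm, method="solve").delta_p
            relaxed = rl.propagate_accessory(adj, 7, prm, method="relax").delta_p
            assert np.max(np.abs(direct - relaxed)) < 1e-6

    def test_diagonal_adjoint_scalar_solve(self, prm):
        """No recurrence: dp_a = 1/(alpha + I_a), all others 0."""
        z = np.zeros((3, 3))
        w = rl.WeightSet.from_dense(np.eye(3) * 0.5, z, z, z)
        I_inp = np.array([0.4, 0.2, 0.9])
        st = _converged_state(w, I_inp, prm)
        adj = rl.linearize_at_fixed_point(st, w, prm, sparse=False)
        acc = rl.propagate_accessory(adj, 1, prm, method="solve")
        assert acc.delta_p[1] == pytest.approx(
            1 / (prm.alpha + st.I_ex[1]), rel=1e-10
        )
        assert acc.delta_p[0] == pytest.approx(0.0, abs=1e-12)
        assert acc.delta_p[2] == pytest.approx(0.0, abs=1e-12)


class TestPlasticityFactors:
    def test_class_factors(self, prm):
        rng = np.random.default_rng(37)
        weights, I_inp = random_mixed_net(rng, n=6, n_inp=2)
        st = _converged_state(weights, I_inp, prm)
        f = rl.plasticity_factors(st, prm)
        l = 2
        p, (I_ex, I_inh, I_mod) = st.p, st.inputs_cache
        assert f["ex"][l] == pytest.approx(
            (prm.beta - p[l]) * (1 + prm.gamma * I_mod[l])
        )
        assert f["mod"][l] == pytest.approx(prm.gamma * (prm.beta - p[l]) * I_ex[l])
        assert f["inh"][l] == pytest.approx(-(prm.zeta + p[l]))
        assert rl.plasticity_factor("ex", st, prm, l) == pytest.approx(f["ex"][l])

    def test_excitatory_factor_without_modulation(self, prm):
        z = np.zeros((2, 2))
        w = rl.WeightSet.from_dense(np.eye(2) * 0.5, z, z, z)
        st = _converged_state(w, np.array([0.5, 0.5]), prm)
        f = rl.plasticity_factors(st, prm)
        np.testing.assert_allclose(f["ex"], prm.beta - st.p)

    def test_modulatory_factor_without_drive_is_zero(self, prm):
        """Modulation without excitatory drive has no effect on learning."""
        n = 2
        W_mod = np.zeros((n, n))
        W_mod[0, 1] = 0.5
        z = np.zeros((n, n))
        W_inp = np.array([[1.0, 0.0]])  # unit 1 has no excitatory input
        w = rl.WeightSet.from_dense(W_inp, z, z, W_mod)
        st = _converged_state(w, np.array([0.7]), prm)
        f = rl.plasticity_factors(st, prm)
        assert st.I_ex[1] == 0.0
        assert f["mod"][1] == pytest.approx(0.0)


class TestWeightUpdate:
    def _setup(self, seed=41):
        rng = np.random.default_rng(seed)
        prm = rl.ModelParams(tol=1e-10, max_steps=50_000)
        weights, I_inp = random_mixed_net(rng, n=8, n_inp=3)
        st = _converged_state(weights, I_inp, prm)
        adj = rl.linearize_at_fixed_point(st, weights, prm, sparse=False)
        acc = rl.propagate_accessory(adj, 7, prm, method="solve")
        return prm, weights, I_inp, st, acc

    @staticmethod
    def _snapshot(w):
        return {c: w.dense(c) for c in ("inp", "ex", "inh", "mod")}

    def test_zero_rpe_or_eta_changes_nothing(self):
        prm, weights, I_inp, st, acc = self._setup()
        before = self._snapshot(weights)
        rl.apply_weight_update(weights, st, acc, rpe=0.0, eta=0.1, I_inp=I_inp, prm=prm)
        rl.apply_weight_update(weights, st, acc, rpe=0.5, eta=0.0, I_inp=I_inp, prm=prm)
        after = self._snapshot(weights)
        for c in before:
            np.testing.assert_array_equal(before[c], after[c])

    def test_update_is_gradient_step(self):
        """One update equals eta * delta * d p_a / d W for every plastic
        entry (finite-difference check)."""
        prm, weights, I_inp, st, acc = self._setup()
        eta, rpe = 1e-3, 0.5
        before = self._snapshot(weights)
        w2 = weights.copy()
        rl.apply_weight_update(w2, st, acc, rpe=rpe, eta=eta, I_inp=I_inp, prm=prm)
        fd = oracles.finite_difference_gradient(weights, I_inp, prm, action=7)
        for c in ("inp", "ex", "inh", "mod"):
            rows, cols = np.nonzero(weights.mask(c))
            got = (w2.dense(c) - before[c])[rows, cols]
            want = eta * rpe * fd[c][rows, cols]
            scale = max(np.max(np.abs(want)), 1e-12)
            assert np.max(np.abs(got - want)) / scale < 1e-4

    def test_fixed_entries_and_structural_zeros_untouched(self):
        prm, weights, I_inp, st, acc = self._setup()
        # freeze the excitatory mask entirely
        weights.plastic_ex[:] = False
        weights._plastic_cache.clear()
        before = self._snapshot(weights)
        rl.apply_weight_update(weights, st, acc, rpe=0.7, eta=0.1, I_inp=I_inp, prm=prm)
        after = self._snapshot(weights)
        np.testing.assert_array_equal(before["ex"], after["ex"])
        for c in ("inp", "inh", "mod"):
            zero_rows, zero_cols = np.nonzero(
                (before[c] == 0) & ~weights.mask(c)
            )
            np.testing.assert_array_equal(after[c][zero_rows, zero_cols], 0.0)

    def test_updates_clip_at_zero(self):
        prm, weights, I_inp, st, acc = self._setup()
        rl.apply_weight_update(
            weights, st, acc, rpe=-50.0, eta=1.0, I_inp=I_inp, prm=prm
        )
        for c in ("inp", "ex", "inh", "mod"):
            assert np.min(weights.dense(c)) >= 0.0

    def test_repeated_updates_shrink_prediction_error(self):
        """Forcing the same action on the same stimulus with small eta
        drives |delta| down monotonically (value improvement)."""
        prm, weights, I_inp, st, acc = self._setup(seed=43)
        action = 7
        reward = 0.6
        errors = []
        for _ in range(15):
            st = rl.relax_to_fixed_point(weights, I_inp, prm)
            assert st.converged
            rpe = rl.reward_prediction_error(reward, st.p[action])
            errors.append(abs(rpe))
            adj = rl.linearize_at_fixed_point(st, weights, prm, sparse=False)
            acc = rl.propagate_accessory(adj, action, prm, method="solve")
            rl.apply_weight_update(
                weights, st, acc, rpe=rpe, eta=0.05, I_inp=I_inp, prm=prm
            )
        assert all(b < a + 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 0.5 * errors[0]
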