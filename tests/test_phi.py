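"""Integrated-information measures: TPM construction, the two Phi_atomic
assemblies, trace-based estimates and lifetime PhiMaxH trajectories."""

import numpy as np
import pytest

from animatphi.brain import Brain
from animatphi.config import PhiConfig
from animatphi.environment import ACTION_MAPPINGS
from animatphi.fixtures import make_fixture
from animatphi.gates import DecomposableGate, DeterministicGate
from animatphi.phi import (TPM, analytic_tpm, phi_atomic_eq3,
                           phi_atomic_from_pairs, phi_atomic_from_tpm,
                           phi_atomic_from_trace, phi_maxh,
                           phi_maxh_trajectory, sampled_tpm,
                           uniform_state_distribution)


def brute_force_phi(tpm: TPM, input_dist=None) -> float:
    """Independent oracle: Phi_atomic via explicit loops over the joint
    distribution of (x_t, x_{t+1}), summing per-node and whole-system
    conditional entropies directly."""
    n = tpm.n_nodes
    size = 2**n
    p = np.full(size, 1.0 / size) if input_dist is None else input_dist
    joint = {}
    for xt in range(size):
        for xt1 in range(size):
            w = p[xt] * tpm.matrix[xt, xt1]
            if w > 0:
                joint[(xt, xt1)] = w

    def H(dist):
        return -sum(v * np.log2(v) for v in dist.values() if v > 0)

    total = 0.0
    for i in range(n):
        j2, m1 = {}, {}
        for (xt, xt1), w in joint.items():
            a, b = (xt >> i) & 1, (xt1 >> i) & 1
            j2[(a, b)] = j2.get((a, b), 0.0) + w
            m1[b] = m1.get(b, 0.0) + w
        total += H(j2) - H(m1)
    marg1 = {}
    for (xt, xt1), w in joint.items():
        marg1[xt1] = marg1.get(xt1, 0.0) + w
    return total - (H(joint) - H(marg1))


class TestAnalyticTPM:
    def test_deterministic_brain_gives_01_matrix(self, swap_brain):
        tpm = analytic_tpm(swap_brain)
        assert np.all(np.isin(tpm.matrix, [0.0, 1.0]))
        np.testing.assert_array_equal(tpm.matrix.sum(axis=1), 1.0)
        # swap permutes bit 0 and bit 1 of the packed state
        for s in range(4):
            assert tpm.matrix[s, ((s & 1) << 1) | (s >> 1)] == 1.0

    def test_fair_coin_gate(self, coin_brain):
        tpm = analytic_tpm(coin_brain)
        np.testing.assert_allclose(tpm.matrix, 0.5)

    def test_two_independent_biased_gates_product_rows(self):
        brain = Brain([DecomposableGate([0], [0], [[0.4], [0.4]]),
                       DecomposableGate([1], [1], [[0.4], [0.4]])],
                      n_nodes=2, n_sensors=0, n_motors=0)
        tpm = analytic_tpm(brain)
        # packed order 00,01,10,11 with bit k = node k
        np.testing.assert_allclose(tpm.matrix[0],
                                   [0.36, 0.24, 0.24, 0.16], atol=1e-12)

    def test_refuses_oversized_state_space(self):
        brain = Brain([], n_nodes=16, n_sensors=4, n_motors=2)
        with pytest.raises(ValueError):
            analytic_tpm(brain, PhiConfig(analytic_max_nodes=12))


class TestSampledTPM:
    def test_deterministic_brain_one_sample_exact(self, xor_brain, rng):
        exact = analytic_tpm(xor_brain).matrix
        est = sampled_tpm(xor_brain, 1, rng).matrix
        np.testing.assert_array_equal(est, exact)

    def test_fair_coin_within_binomial_band(self, coin_brain):
        est = sampled_tpm(coin_brain, 10_000,
                          np.random.default_rng(0)).matrix
        np.testing.assert_allclose(est, 0.5, atol=0.02)

    def test_same_seed_same_estimate(self, coin_brain):
        a = sampled_tpm(coin_brain, 100, np.random.default_rng(5)).matrix
        b = sampled_tpm(coin_brain, 100, np.random.default_rng(5)).matrix
        np.testing.assert_array_equal(a, b)

    def test_convergence_rate_inverse_sqrt(self):
        """Max row-wise L1 error shrinks ~10x from k=100 to k=10000."""
        brain = Brain([DecomposableGate([0], [0], [[0.3], [0.6]]),
                       DecomposableGate([1], [1], [[0.7], [0.2]])],
                      n_nodes=2, n_sensors=0, n_motors=0)
        exact = analytic_tpm(brain).matrix
        errs = {}
        for k in (100, 10_000):
            reps = []
            for seed in range(5):
                est = sampled_tpm(brain, k,
                                  np.random.default_rng(seed)).matrix
                reps.append(np.abs(est - exact).sum(axis=1).max())
            errs[k] = np.mean(reps)
        ratio = errs[10_000] / errs[100]
        assert ratio < 0.33  # consistent with O(k^-1/2) = 0.1 expected

    def test_estimator_unaffected_by_learning_state(self,
                                                    feedback_probe_brain,
                                                    rng):
        before = feedback_probe_brain.tables_fingerprint()
        sampled_tpm(feedback_probe_brain, 64, rng)
        assert feedback_probe_brain.tables_fingerprint() == before


class TestClosedFormPhi:
    def test_independent_copy_is_zero(self, copy_brain):
        tpm = analytic_tpm(copy_brain)
        res = phi_atomic_from_tpm(tpm)
        assert res.phi_atomic == pytest.approx(0.0, abs=1e-12)
        assert res.phi_atomic == pytest.approx(brute_force_phi(tpm),
                                               abs=1e-9)

    def test_swap_is_two_bits(self, swap_brain):
        tpm = analytic_tpm(swap_brain)
        res = phi_atomic_from_tpm(tpm)
        assert res.phi_atomic == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(res.per_node_cond_h, 1.0)
        assert res.joint_cond_h == pytest.approx(0.0, abs=1e-12)
        assert brute_force_phi(tpm) == pytest.approx(2.0, abs=1e-9)

    def test_xor_broadcast_is_one_bit(self, xor_brain):
        tpm = analytic_tpm(xor_brain)
        res = phi_atomic_from_tpm(tpm)
        assert res.phi_atomic == pytest.approx(1.0, abs=1e-12)
        assert brute_force_phi(tpm) == pytest.approx(1.0, abs=1e-9)

    def test_factorizing_tpm_has_zero_phi(self):
        """When the TPM factorises over nodes under the input distribution,
        the whole is exactly the sum of its parts."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            f = rng.uniform(0.05, 0.95, size=2)
            brain = Brain([DecomposableGate([0], [0], [[f[0]], [f[0]]]),
                           DecomposableGate([1], [1], [[f[1]], [f[1]]])],
                          n_nodes=2, n_sensors=0, n_motors=0)
            res = phi_atomic_from_tpm(analytic_tpm(brain))
            assert res.phi_atomic == pytest.approx(0.0, abs=1e-9)
            assert res.nonindependence == pytest.approx(0.0, abs=1e-9)


class TestAssemblyIdentity:
    def test_equivalence_on_random_tpms(self):
        """The conditional-entropy and mutual-information assemblies are
        algebraically identical; verify numerically on random 3-node TPMs
        with uniform and non-uniform input distributions."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            m = rng.random((8, 8))
            m /= m.sum(axis=1, keepdims=True)
            tpm = TPM(3, m)
            nonuni = rng.random(8)
            nonuni /= nonuni.sum()
            for dist in (None, nonuni):
                a = phi_atomic_from_tpm(tpm, dist)
                b = phi_atomic_eq3(tpm, dist)
                worst = max(worst, abs(a.phi_atomic - b.phi_atomic))
                assert a.phi_atomic == pytest.approx(b.phi_atomic, abs=1e-9)
                # internal cross-assembly of a single result object
                assert a.phi_atomic == pytest.approx(a.phi_mi_assembly,
                                                     abs=1e-9)
        assert worst < 1e-9

    def test_components_match_oracle_on_fixtures(self, swap_brain, xor_brain,
                                                 copy_brain):
        for brain in (swap_brain, xor_brain, copy_brain):
            tpm = analytic_tpm(brain)
            a = phi_atomic_from_tpm(tpm)
            b = phi_atomic_eq3(tpm)
            np.testing.assert_allclose(a.per_node_i, b.per_node_i, atol=1e-9)
            assert a.i_sys == pytest.approx(b.i_sys, abs=1e-9)
            assert a.nonindependence == pytest.approx(b.nonindependence,
                                                      abs=1e-9)

    def test_independent_nodes_have_zero_nonindependence(self, copy_brain):
        res = phi_atomic_eq3(analytic_tpm(copy_brain))
        assert res.nonindependence == pytest.approx(0.0, abs=1e-12)
        assert res.i_sys == pytest.approx(res.per_node_i.sum(), abs=1e-9)


class TestTracePhi:
    def test_constant_trace_is_zero(self):
        res = phi_atomic_from_trace([5] * 100, n_nodes=3)
        assert res.phi_atomic == 0.0

    def test_alternating_trace_is_zero(self):
        """01 <-> 10: each node's next value is determined by its own
        current value in the empirical joint, so nothing is integrated."""
        res = phi_atomic_from_trace([1, 2] * 64, n_nodes=2)
        assert res.phi_atomic == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.per_node_cond_h, 0.0, atol=1e-12)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            phi_atomic_from_trace([3], n_nodes=2)

    def test_swap_transitions_at_uniform_stationarity(self, swap_brain, rng):
        """Plug-in estimate over 10,000 transitions sampled with uniform
        start states recovers the closed-form 2 bits."""
        xt = rng.integers(4, size=10_000)
        xt1 = np.array([swap_brain.next_state_free(int(s), rng) for s in xt])
        res = phi_atomic_from_pairs(xt, xt1, n_nodes=2)
        assert res.phi_atomic == pytest.approx(2.0, abs=0.05)


class TestPhiMaxH:
    def test_static_brain_flat_trajectory(self, open_world, rng):
        """A brain without feedback gates has the same TPM at every time
        point, so PhiMaxH is identical at all checkpoints."""
        brain = Brain([DeterministicGate([0], [5], [0, 1]),
                       DeterministicGate([5], [6], [1, 0]),
                       DecomposableGate([6], [7], [[0.3], [0.8]])],
                      n_nodes=8, n_sensors=4, n_motors=2)
        config = PhiConfig(checkpoint_stride=50)
        traj = phi_maxh_trajectory(brain, open_world, ACTION_MAPPINGS[0],
                                   rng, lifetime=512, config=config)
        assert len(traj.timesteps) == 11
        assert np.ptp(traj.phi_values) <= 1e-12
        assert traj.slope == pytest.approx(0.0, abs=1e-15)

    def test_checkpoint_count(self, open_world, rng):
        brain = Brain([], n_nodes=8, n_sensors=4, n_motors=2)
        traj = phi_maxh_trajectory(brain, open_world, ACTION_MAPPINGS[0],
                                   rng, lifetime=512,
                                   config=PhiConfig(checkpoint_stride=50))
        np.testing.assert_array_equal(traj.timesteps, range(0, 501, 50))

    def test_learning_brain_trajectory_moves(self, rng):
        """A feedback gate pushed toward determinism by constant positive
        reinforcement changes the TPM, hence PhiMaxH, over the lifetime."""
        brain = make_fixture("feedback_probe_brain", delta=0.2)
        phi_birth = phi_maxh(brain)
        for _ in range(40):
            brain.step([1, 0], rng)
        phi_later = phi_maxh(brain.snapshot())
        assert phi_later != pytest.approx(phi_birth, abs=1e-6)

    def test_swap_brain_phi_maxh_closed_form(self, swap_brain):
        assert phi_maxh(swap_brain) == pytest.approx(2.0, abs=1e-12)

    def test_sampled_matches_analytic_for_task_brain(self):
        """For a 16-node brain the uniform-H_t construction is sampled; on a
        deterministic brain sampling is exact, so the restricted analytic
        value must agree."""
        brain = Brain([DeterministicGate([6], [7], [0, 1]),
                       DeterministicGate([7], [6], [1, 0])])
        sampled = phi_maxh(brain, PhiConfig(samples_per_state=1),
                           np.random.default_rng(0))
        # same computation on the 2-node closed system plus 14 free nodes:
        # free/decaying nodes contribute nothing to either assembly term
        core = Brain([DeterministicGate([0], [1], [0, 1]),
                      DeterministicGate([1], [0], [1, 0])],
                     n_nodes=2, n_sensors=0, n_motors=0)
        expected = phi_atomic_from_tpm(analytic_tpm(core)).phi_atomic
        assert sampled == pytest.approx(expected, abs=1e-9)

    def test_node_set_restriction_is_explicit(self, rng):
        brain = Brain([DeterministicGate([6], [7], [0, 1]),
                       DeterministicGate([7], [6], [1, 0])])
        full = phi_maxh(brain, PhiConfig(samples_per_state=1),
                        np.random.default_rng(0))
        no_sensors = phi_maxh(brain, PhiConfig(node_set="exclude_sensors"),
                              np.random.default_rng(0))
        assert no_sensors == pytest.approx(full, abs=1e-9)
        with pytest.raises(ValueError):
            phi_maxh(brain, PhiConfig(node_set="hidden_only"))


class TestUniformDistribution:
    def test_uniform_helper(self):
        d = uniform_state_distribution(4)
        assert d.shape == (16,)
        assert d.sum() == pytest.approx(1.0)
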