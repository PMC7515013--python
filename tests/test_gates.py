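"""Gate algebra: factor expansion, decomposability, feedback learning,
and gate-level mutual information."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from animatphi.gates import (DecomposableFeedbackGate, DecomposableGate,
                             DeterministicGate, FeedbackParams, GateTable,
                             LegacyFeedbackGate, NotDecomposableError,
                             P_MIN, factors_from_row, gate_from_dict,
                             row_from_factors, table_mutual_information,
                             table_row_entropy)


def _probe_gate(factors, delta=0.1, history=1, p_min=P_MIN):
    fb = FeedbackParams(pos_node=0, neg_node=1, history_length=history,
                        pos_deltas=np.full(3, delta),
                        neg_deltas=np.full(3, delta))
    factors = np.atleast_2d(factors)
    n_out = factors.shape[1]
    return DecomposableFeedbackGate([2], list(range(2, 2 + n_out)), factors,
                                    fb, p_min=p_min)


class TestFactorAlgebra:
    @pytest.mark.parametrize("factors,expected", [
        ((0.4, 0.4), [0.36, 0.24, 0.24, 0.16]),
        ((0.0,), [1.0, 0.0]),
        ((1.0, 1.0), [0.0, 0.0, 0.0, 1.0]),
    ])
    def test_row_from_factors(self, factors, expected):
        np.testing.assert_allclose(row_from_factors(factors), expected,
                                   atol=1e-12)

    def test_row_from_factors_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            row_from_factors([0.5, 1.2])

    @pytest.mark.parametrize("row,expected", [
        ([0.36, 0.24, 0.24, 0.16], (0.4, 0.4)),
        ([1.0, 0.0, 0.0, 0.0], (0.0, 0.0)),
    ])
    def test_factors_from_row(self, row, expected):
        np.testing.assert_allclose(factors_from_row(row), expected,
                                   atol=1e-12)

    def test_anticorrelated_row_is_not_decomposable(self):
        # bits individually near-fair but strongly dependent
        with pytest.raises(NotDecomposableError):
            factors_from_row([0.02, 0.48, 0.48, 0.02])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=P_MIN, max_value=1 - P_MIN),
                    min_size=1, max_size=4))
    def test_round_trip(self, factors):
        np.testing.assert_allclose(
            factors_from_row(row_from_factors(factors)), factors, atol=1e-9)


class TestGateUpdate:
    def test_deterministic_ignores_rng(self, rng):
        gate = DeterministicGate([0, 1], [2], [0, 1, 1, 0])
        assert [gate.update(p, rng) for p in range(4)] == [0, 1, 1, 0]

    def test_fixed_seed_reproducible(self):
        gate = _probe_gate([[0.5, 0.5], [0.5, 0.5]])
        draws1 = [gate.update(0, np.random.default_rng(7)) for _ in range(20)]
        draws2 = [gate.update(0, np.random.default_rng(7)) for _ in range(20)]
        assert draws1 == draws2

    def test_sampling_frequency_matches_row(self, rng):
        gate = DecomposableGate([0], [1], [[0.5], [0.5]])
        draws = np.array([gate.update(0, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 0.5) < 0.02  # ~4 sigma binomial band

    def test_input_pattern_out_of_range(self, rng):
        gate = DecomposableGate([0], [1], [[0.5], [0.5]])
        with pytest.raises(ValueError):
            gate.update(5, rng)


class TestFeedback:
    def test_positive_moves_factor_toward_emitted_bit(self, rng):
        gate = _probe_gate([[0.5, 0.5], [0.5, 0.5]])
        gate.history.appendleft((0, 0b11))  # both bits emitted as 1
        gate.apply_feedback(+1, rng)
        np.testing.assert_allclose(gate.factors[0], [0.6, 0.6])

    def test_negative_moves_factor_away(self, rng):
        gate = _probe_gate([[0.5, 0.5], [0.5, 0.5]])
        gate.history.appendleft((0, 0b11))
        gate.apply_feedback(-1, rng)
        np.testing.assert_allclose(gate.factors[0], [0.4, 0.4])

    def test_clamping_at_p_min(self, rng):
        gate = _probe_gate([[0.95, 0.95], [0.5, 0.5]], delta=0.1, p_min=0.01)
        gate.history.appendleft((0, 0b11))
        gate.apply_feedback(+1, rng)
        np.testing.assert_allclose(gate.factors[0], [0.99, 0.99])

    def test_empty_history_is_noop(self, rng):
        gate = _probe_gate([[0.5, 0.5], [0.5, 0.5]])
        before = gate.factors.copy()
        gate.apply_feedback(+1, rng)
        np.testing.assert_array_equal(gate.factors, before)

    def test_feedback_reaches_all_remembered_depths(self, rng):
        gate = _probe_gate([[0.5], [0.5]], delta=0.1, history=2)
        gate.update(0, rng)
        gate.update(1, rng)
        gate.apply_feedback(+1, rng)
        # both remembered decisions moved their factor by 0.1
        assert not np.allclose(gate.factors, 0.5)
        moved = np.abs(gate.factors - 0.5)
        assert np.count_nonzero(np.isclose(moved, 0.1)) == 2

    def test_monotone_sharpening_until_clamp(self, rng):
        gate = _probe_gate([[0.5, 0.5], [0.5, 0.5]], delta=0.05)
        entropies = []
        for _ in range(12):
            gate.history.clear()
            gate.history.appendleft((0, 0b10))
            gate.apply_feedback(+1, rng)
            entropies.append(table_row_entropy(gate.table.rows[0]))
        diffs = np.diff([table_row_entropy(row_from_factors([0.5, 0.5]))]
                        + entropies)
        # strictly decreasing until both factors hit the clamp
        assert np.all(diffs[:9] < 0)

    def test_reset_learning_restores_birth_table(self, rng):
        gate = _probe_gate([[0.3, 0.7], [0.5, 0.5]])
        gate.update(0, rng)
        gate.apply_feedback(+1, rng)
        gate.reset_learning()
        np.testing.assert_array_equal(gate.factors, [[0.3, 0.7], [0.5, 0.5]])

    def test_legacy_feedback_renormalises(self, rng):
        fb = FeedbackParams(0, 1, 1, np.full(3, 0.1), np.full(3, 0.1))
        gate = LegacyFeedbackGate([2], [3], [[0.25, 0.75], [0.5, 0.5]], fb)
        gate.update(0, rng)
        gate.apply_feedback(+1, rng)
        np.testing.assert_allclose(gate.rows.sum(axis=1), 1.0, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_decomposability_closure(self, seed):
        """Rows stay factorizable and row-stochastic after any random
        feedback sequence."""
        r = np.random.default_rng(seed)
        i, o = int(r.integers(1, 4)), int(r.integers(1, 4))
        fb = FeedbackParams(0, 1, int(r.integers(1, 4)),
                            r.random(3) * 0.5, r.random(3) * 0.5)
        gate = DecomposableFeedbackGate(
            list(r.integers(0, 4, size=i)), list(r.integers(0, 4, size=o)),
            r.uniform(P_MIN, 1 - P_MIN, size=(2**i, o)), fb)
        for _ in range(30):
            gate.update(int(r.integers(2**i)), r)
            gate.apply_feedback(1 if r.random() < 0.5 else -1, r)
        table = gate.table
        np.testing.assert_allclose(table.rows.sum(axis=1), 1.0, atol=1e-9)
        for row in table.rows:
            factors_from_row(row)  # must not raise


class TestMutualInformation:
    def test_bijective_deterministic_table_is_noiseless(self):
        gate = DeterministicGate([0, 1], [2, 3], [0, 1, 2, 3])
        assert table_mutual_information(gate.table) == pytest.approx(2.0)

    def test_identical_rows_carry_nothing(self):
        rows = np.tile([0.1, 0.2, 0.3, 0.4], (4, 1))
        table = GateTable(2, 2, rows)
        assert table_mutual_information(table) == pytest.approx(0.0, abs=1e-12)

    def test_binary_symmetric_channel_closed_form(self):
        table = GateTable(1, 1, [[0.9, 0.1], [0.1, 0.9]])
        hb = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
        assert table_mutual_information(table) == pytest.approx(1 - hb,
                                                                abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        r = np.random.default_rng(seed)
        i, o = int(r.integers(1, 4)), int(r.integers(1, 4))
        rows = r.random((2**i, 2**o))
        rows /= rows.sum(axis=1, keepdims=True)
        table = GateTable(i, o, rows)
        # independent oracle: explicit double sum over the joint
        mi = 0.0
        px = 1.0 / 2**i
        py = rows.mean(axis=0)
        for a in range(2**i):
            for b in range(2**o):
                j = px * rows[a, b]
                if j > 0:
                    mi += j * np.log2(j / (px * py[b]))
        assert table_mutual_information(table) == pytest.approx(mi, abs=1e-6)
        assert -1e-9 <= table_mutual_information(table) <= min(i, o) + 1e-9


class TestSerialization:
    def test_json_round_trip_all_types(self, rng):
        fb = FeedbackParams(3, 7, 2, np.full(3, 0.1), np.full(3, 0.2))
        gates = [
            DeterministicGate([0, 1], [2], [0, 1, 1, 0]),
            DecomposableGate([0], [1, 2], [[0.3, 0.7], [0.2, 0.8]]),
            DecomposableFeedbackGate([0], [1], [[0.5], [0.5]], fb),
            LegacyFeedbackGate([0], [1], [[0.4, 0.6], [0.5, 0.5]], fb),
        ]
        for gate in gates:
            clone = gate_from_dict(gate.to_dict())
            assert type(clone) is type(gate)
            np.testing.assert_allclose(clone.table.rows, gate.table.rows)
            assert clone.input_addrs == gate.input_addrs
            assert clone.output_addrs == gate.output_addrs


class TestInvariants:
    def test_row_stochastic_after_mixed_usage(self, rng):
        gate = _probe_gate(np.full((2, 3), 0.5), delta=0.2, history=3)
        for _ in range(200):
            gate.update(int(rng.integers(2)), rng)
            gate.apply_feedback(1 if rng.random() < 0.5 else -1, rng)
        np.testing.assert_allclose(gate.table.rows.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_deterministic_table_invariant(self):
        gate = DeterministicGate([0], [1, 2], [3, 0])
        assert gate.table.is_deterministic
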