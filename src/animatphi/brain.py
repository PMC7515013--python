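"""The Markov Brain: binary nodes updated synchronously by a gate list.

The navigation task uses 16 nodes: indices 0-3 are sensors (written only by
the environment), 4-5 are motors, 6-15 are hidden memory.  Fixture brains
may use other layouts.

Update semantics (one ``step``):

1. sensor values are written into nodes ``0..n_sensors-1`` of the current
   state;
2. every gate reads the current (time ``t``) state and samples its output
   pattern; outputs are OR-combined into a fresh time ``t+1`` buffer.
   Writes aimed at sensor nodes are discarded -- sensors are owned by the
   environment and simply persist through the update.  Motor/hidden nodes
   written by no gate are 0;
3. if learning is enabled, each feedback gate whose positive (negative)
   reinforcement node is 1 in the *new* state applies positive-then-negative
   feedback to its remembered decisions.

With learning disabled, gate tables are bit-identical before and after any
episode: the brain is static, as for organisms without neuroplasticity.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

from .gates import Gate
from .genome import DEFAULT_GATE_TYPES, decode_genome


class Brain:
    """A network of logic gates over binary nodes.

    Parameters
    ----------
    gates
        Decoded gate list; addresses must be < ``n_nodes``.
    n_nodes, n_sensors, n_motors
        Node layout; motors occupy the ``n_motors`` indices after the
        sensors.  Defaults are the navigation-task layout (16/4/2).
    learning_enabled
        When False, reinforcement is never applied (static brain).
    """

    def __init__(self, gates: Sequence[Gate], n_nodes: int = 16,
                 n_sensors: int = 4, n_motors: int = 2,
                 learning_enabled: bool = True):
        if n_sensors + n_motors > n_nodes:
            raise ValueError("node layout exceeds node count")
        self.n_nodes = n_nodes
        self.n_sensors = n_sensors
        self.n_motors = n_motors
        self.learning_enabled = learning_enabled
        self.gates = list(gates)
        for gate in self.gates:
            addrs = gate.input_addrs + gate.output_addrs
            if any(a < 0 or a >= n_nodes for a in addrs):
                raise ValueError("gate address out of node range")
        self.node_states = np.zeros(n_nodes, dtype=np.uint8)

    @classmethod
    def from_genome(cls, genome, n_nodes: int = 16, n_sensors: int = 4,
                    n_motors: int = 2, gate_types=DEFAULT_GATE_TYPES,
                    learning_enabled: bool = True, **decode_kwargs) -> "Brain":
        gates = decode_genome(genome, n_nodes=n_nodes, gate_types=gate_types,
                              **decode_kwargs)
        return cls(gates, n_nodes=n_nodes, n_sensors=n_sensors,
                   n_motors=n_motors, learning_enabled=learning_enabled)

    # -- update ----------------------------------------------------------

    def _input_pattern(self, gate: Gate, state: np.ndarray) -> int:
        pattern = 0
        for addr in gate.input_addrs:
            pattern = (pattern << 1) | int(state[addr])
        return pattern

    def step(self, sensor_bits, rng: np.random.Generator) -> np.ndarray:
        """One synchronous update; returns the motor bit vector."""
        state = self.node_states
        sensors = np.asarray(sensor_bits, dtype=np.uint8)
        if sensors.shape != (self.n_sensors,):
            raise ValueError(f"expected {self.n_sensors} sensor bits")
        state[: self.n_sensors] = sensors

        new = np.zeros(self.n_nodes, dtype=np.uint8)
        new[: self.n_sensors] = state[: self.n_sensors]
        for gate in self.gates:
            out = gate.update(self._input_pattern(gate, state), rng)
            o = gate.n_outputs
            for j, addr in enumerate(gate.output_addrs):
                if addr < self.n_sensors:
                    continue  # sensors are environment-owned
                new[addr] |= (out >> (o - 1 - j)) & 1
        self.node_states = new

        if self.learning_enabled:
            for gate in self.gates:
                if not gate.feedback_capable:
                    continue
                if new[gate.feedback.pos_node]:
                    gate.apply_feedback(+1, rng)
                if new[gate.feedback.neg_node]:
                    gate.apply_feedback(-1, rng)
        return new[self.n_sensors : self.n_sensors + self.n_motors].copy()

    def next_state_free(self, state_index: int,
                        rng: np.random.Generator) -> int:
        """One update from an arbitrary packed state with every node free
        (no sensor clamping, no learning, no history recording).

        This is the transition the state-to-state TPM describes: sensors
        self-copy, all other unwritten nodes decay to 0.  Packed states use
        bit ``k`` (LSB) for node ``k``.
        """
        state = np.array([(state_index >> k) & 1 for k in range(self.n_nodes)],
                         dtype=np.uint8)
        next_idx = 0
        for k in range(self.n_sensors):
            next_idx |= int(state[k]) << k
        for gate in self.gates:
            row = gate.table.rows[self._input_pattern(gate, state)]
            out = Gate._sample(row, rng)
            o = gate.n_outputs
            for j, addr in enumerate(gate.output_addrs):
                if addr < self.n_sensors:
                    continue
                next_idx |= (((out >> (o - 1 - j)) & 1) << addr)
        return next_idx

    # -- reset -----------------------------------------------------------

    def reset(self, scope: str = "both") -> "Brain":
        """Reset node states, learned tables, or both.

        ``states``: zero all nodes and clear feedback histories.
        ``learning``: restore every gate table to its genome-encoded values.
        ``both``: both.  Idempotent.
        """
        if scope not in ("states", "learning", "both"):
            raise ValueError(f"unknown reset scope {scope!r}")
        if scope in ("states", "both"):
            self.node_states[:] = 0
            for gate in self.gates:
                gate.reset_history()
        if scope in ("learning", "both"):
            for gate in self.gates:
                gate.reset_learning()
        return self

    # -- misc ------------------------------------------------------------

    def packed_state(self) -> int:
        """Current node states packed into an int (bit k = node k)."""
        return int(sum(int(b) << k for k, b in enumerate(self.node_states)))

    def snapshot(self) -> "Brain":
        """Deep copy capturing the current (possibly learned) gate tables."""
        return copy.deepcopy(self)

    @property
    def feedback_gates(self):
        return [g for g in self.gates if g.feedback_capable]

    def tables_fingerprint(self) -> bytes:
        """Byte string identifying all current gate tables (for static-brain
        contracts and archive hashing)."""
        parts = [np.ascontiguousarray(g.table.rows).tobytes() for g in self.gates]
        return b"".join(parts)
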