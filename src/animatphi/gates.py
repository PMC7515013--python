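"""Logic gates for Markov Brains.

A Markov Brain is a network of small logic units ("gates"), each mapping a
pattern over up to four binary input nodes to a pattern over up to four
binary output nodes through a ``2^i x 2^o`` row-stochastic probability
table.  Four gate families are provided:

* :class:`DeterministicGate` -- one certain output pattern per input pattern.
* :class:`DecomposableGate` -- a probabilistic gate whose per-input-pattern
  output distribution factorises into independent per-output-bit Bernoulli
  probabilities ("factors").  Decomposability is the property required for a
  valid information-integration analysis: output bits may not share
  information within a single gate.
* :class:`DecomposableFeedbackGate` -- a decomposable gate whose factors are
  nudged during the organism's lifetime by internally generated positive or
  negative reinforcement (a model of long-term potentiation).  Because the
  per-bit factors are updated individually and the table is rebuilt from
  them, the gate stays decomposable after arbitrarily many updates.
* :class:`LegacyFeedbackGate` -- the earlier, non-decomposable feedback gate
  that shifts raw row entries and renormalises; kept behind a flag for
  comparison only.

Bit conventions: for a pattern over bits ``(b0, .., b_{k-1})`` the pattern
index is big-endian, ``index = sum(b_j << (k-1-j))``, so factor 0 / input
address 0 is the most significant bit.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, xlogy

logger = logging.getLogger(__name__)

#: default clamp keeping factors strictly inside (0, 1) so tables stay
#: stochastic and learning can always be undone
P_MIN = 0.01
#: upper bound for genome-encoded feedback deltas
DELTA_MAX = 0.5
#: deepest reinforceable memory of past (input, output) decisions
MAX_HISTORY = 3

_ROW_TOL = 1e-9


class NotDecomposableError(ValueError):
    """Raised when a probability row cannot be written as a product of
    independent per-bit Bernoulli distributions."""


def _pattern_bits(n_bits: int) -> np.ndarray:
    """(2^n, n) array of bit values, big-endian (column 0 = MSB)."""
    idx = np.arange(2**n_bits)
    shifts = np.arange(n_bits - 1, -1, -1)
    return (idx[:, None] >> shifts[None, :]) & 1


def row_from_factors(factors) -> np.ndarray:
    """Expand per-bit on-probabilities into a full output-pattern row.

    The entry for pattern ``b`` is the product over bits of ``factor`` where
    the bit is set and ``1 - factor`` where it is clear, e.g. for factors
    ``(a, b)`` the pattern ``01`` has probability ``(1-a)*b``.
    """
    f = np.asarray(factors, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("factors must be a non-empty 1-D sequence")
    if np.any((f < 0.0) | (f > 1.0)):
        raise ValueError(f"factors must lie in [0, 1], got {f}")
    bits = _pattern_bits(f.size)
    return np.prod(np.where(bits == 1, f, 1.0 - f), axis=1)


def factors_from_row(row) -> np.ndarray:
    """Invert :func:`row_from_factors`, or raise :class:`NotDecomposableError`.

    Returns the per-bit marginal on-probabilities iff their outer product
    reconstructs the row within ``1e-9``.  Rows such as
    ``[0.02, 0.48, 0.48, 0.02]`` (anti-correlated bits) are rejected rather
    than silently approximated.
    """
    r = np.asarray(row, dtype=float)
    n_patterns = r.size
    o = int(round(np.log2(n_patterns)))
    if 2**o != n_patterns:
        raise ValueError("row length must be a power of two")
    if abs(r.sum() - 1.0) > 1e-6:
        raise ValueError(f"row must sum to 1, sums to {r.sum()}")
    bits = _pattern_bits(o)
    marginals = bits.T @ r  # P(bit_j = 1)
    if np.max(np.abs(row_from_factors(marginals) - r)) > _ROW_TOL:
        raise NotDecomposableError(
            "row is not a product of independent per-bit probabilities"
        )
    return marginals


@dataclass
class GateTable:
    """A ``2^i x 2^o`` row-stochastic state-transition table."""

    n_inputs: int
    n_outputs: int
    rows: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if not (1 <= self.n_inputs <= 4 and 1 <= self.n_outputs <= 4):
            raise ValueError("gate arity must be 1-4 inputs and outputs")
        if self.rows.shape != (2**self.n_inputs, 2**self.n_outputs):
            raise ValueError(
                f"rows shape {self.rows.shape} does not match arity "
                f"({self.n_inputs} in, {self.n_outputs} out)"
            )
        self.validate()

    def validate(self):
        if np.any((self.rows < -_ROW_TOL) | (self.rows > 1 + _ROW_TOL)):
            raise ValueError("table entries must lie in [0, 1]")
        sums = self.rows.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-6:
            raise ValueError(f"rows must sum to 1, got sums {sums}")

    @property
    def is_deterministic(self) -> bool:
        return bool(np.all(np.isclose(self.rows.max(axis=1), 1.0)))


def table_mutual_information(table: GateTable) -> float:
    """Analytic I(input : output) in bits for a uniform input distribution."""
    joint = table.rows / table.rows.shape[0]
    indep = np.outer(joint.sum(axis=1), joint.sum(axis=0))
    return float(rel_entr(joint, indep).sum() / np.log(2.0))


def table_row_entropy(row: np.ndarray) -> float:
    """Shannon entropy of one output row, in bits (0 log 0 = 0)."""
    return float(-xlogy(row, row).sum() / np.log(2.0))


@dataclass
class FeedbackParams:
    """Genome-encoded reinforcement wiring of a feedback gate.

    ``pos_node`` / ``neg_node`` are brain node addresses; when the addressed
    node is 1 after an update, positive (negative) reinforcement is applied
    to every remembered decision.  ``pos_deltas`` / ``neg_deltas`` hold one
    probability increment per remembered time depth (most recent first).
    """

    pos_node: int
    neg_node: int
    history_length: int
    pos_deltas: np.ndarray
    neg_deltas: np.ndarray

    def __post_init__(self):
        if self.history_length not in (0, 1, 2, 3):
            raise ValueError("history_length must be 0..3")
        self.pos_deltas = np.asarray(self.pos_deltas, dtype=float)
        self.neg_deltas = np.asarray(self.neg_deltas, dtype=float)
        for d in (self.pos_deltas, self.neg_deltas):
            if d.size < self.history_length:
                raise ValueError("need one delta per remembered time depth")
            if np.any(d < 0):
                raise ValueError("feedback deltas must be non-negative")


class Gate:
    """Common interface of all gate types."""

    feedback_capable = False

    def __init__(self, input_addrs, output_addrs):
        self.input_addrs = list(int(a) for a in input_addrs)
        self.output_addrs = list(int(a) for a in output_addrs)
        if not (1 <= len(self.input_addrs) <= 4):
            raise ValueError("gates take 1-4 inputs")
        if not (1 <= len(self.output_addrs) <= 4):
            raise ValueError("gates produce 1-4 outputs")

    @property
    def n_inputs(self) -> int:
        return len(self.input_addrs)

    @property
    def n_outputs(self) -> int:
        return len(self.output_addrs)

    @property
    def table(self) -> GateTable:
        raise NotImplementedError

    def update(self, input_pattern: int, rng: np.random.Generator) -> int:
        """Sample an output pattern for ``input_pattern`` from the current
        table.  Feedback-capable gates also record the decision."""
        rows = self.table.rows
        if not 0 <= input_pattern < rows.shape[0]:
            raise ValueError(f"input pattern {input_pattern} out of range")
        out = self._sample(rows[input_pattern], rng)
        self._record(input_pattern, out)
        return out

    @staticmethod
    def _sample(row: np.ndarray, rng: np.random.Generator) -> int:
        r = rng.random()
        acc = 0.0
        for k, p in enumerate(row):
            acc += p
            if r < acc:
                return k
        return len(row) - 1  # guard against rounding at the top end

    def _record(self, input_pattern: int, output_pattern: int):
        pass

    def apply_feedback(self, sign: int, rng: np.random.Generator):
        raise TypeError(f"{type(self).__name__} has no feedback capability")

    def reset_history(self):
        pass

    def reset_learning(self):
        pass

    def mutual_information(self) -> float:
        return table_mutual_information(self.table)

    def to_dict(self) -> dict:
        raise NotImplementedError


class DeterministicGate(Gate):
    """One certain output pattern per input pattern."""

    def __init__(self, input_addrs, output_addrs, output_map):
        super().__init__(input_addrs, output_addrs)
        self.output_map = np.asarray(output_map, dtype=np.int64)
        if self.output_map.shape != (2**self.n_inputs,):
            raise ValueError("need one output pattern per input pattern")
        if np.any((self.output_map < 0) | (self.output_map >= 2**self.n_outputs)):
            raise ValueError("output pattern out of range")

    @property
    def table(self) -> GateTable:
        rows = np.zeros((2**self.n_inputs, 2**self.n_outputs))
        rows[np.arange(rows.shape[0]), self.output_map] = 1.0
        return GateTable(self.n_inputs, self.n_outputs, rows)

    def update(self, input_pattern, rng):
        return int(self.output_map[input_pattern])

    def to_dict(self):
        return {
            "type": "deterministic",
            "inputs": self.input_addrs,
            "outputs": self.output_addrs,
            "output_map": self.output_map.tolist(),
        }


class DecomposableGate(Gate):
    """Probabilistic gate with independent per-output-bit probabilities."""

    def __init__(self, input_addrs, output_addrs, factors, p_min: float = P_MIN):
        super().__init__(input_addrs, output_addrs)
        self.p_min = float(p_min)
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (2**self.n_inputs, self.n_outputs):
            raise ValueError(
                f"factors shape {factors.shape} does not match arity "
                f"({self.n_inputs} in, {self.n_outputs} out)"
            )
        if np.any((factors < 0) | (factors > 1)):
            raise ValueError("factors must lie in [0, 1]")
        self.factors = factors.copy()
        self._birth_factors = factors.copy()

    @property
    def table(self) -> GateTable:
        rows = np.vstack([row_from_factors(f) for f in self.factors])
        return GateTable(self.n_inputs, self.n_outputs, rows)

    def reset_learning(self):
        self.factors = self._birth_factors.copy()

    def to_dict(self):
        return {
            "type": "decomposable",
            "inputs": self.input_addrs,
            "outputs": self.output_addrs,
            "factors": self.factors.tolist(),
            "p_min": self.p_min,
        }


class DecomposableFeedbackGate(DecomposableGate):
    """Decomposable gate that learns from internal reinforcement.

    Each update appends the (input, output) decision to a ring buffer of at
    most ``history_length`` entries.  When reinforcement arrives, every
    remembered decision is revisited, most recent first: for positive
    feedback each factor moves by that depth's delta *toward* the emitted
    bit value, for negative feedback *away* from it, clamped to
    ``[p_min, 1 - p_min]``.  Rows are rebuilt from factors on demand, so the
    gate remains decomposable by construction.
    """

    feedback_capable = True

    def __init__(self, input_addrs, output_addrs, factors,
                 feedback: FeedbackParams, p_min: float = P_MIN):
        super().__init__(input_addrs, output_addrs, factors, p_min=p_min)
        self.feedback = feedback
        self.history: deque = deque(maxlen=feedback.history_length)

    def _record(self, input_pattern, output_pattern):
        if self.feedback.history_length > 0:
            self.history.appendleft((input_pattern, output_pattern))

    def apply_feedback(self, sign: int, rng: np.random.Generator):
        if len(self.history) == 0:
            logger.debug("feedback on %s with empty history: no-op", self)
            return
        deltas = self.feedback.pos_deltas if sign > 0 else self.feedback.neg_deltas
        lo, hi = self.p_min, 1.0 - self.p_min
        for depth, (inp, out) in enumerate(self.history):
            delta = float(deltas[depth])
            for j in range(self.n_outputs):
                bit = (out >> (self.n_outputs - 1 - j)) & 1
                toward = delta if bit else -delta
                move = toward if sign > 0 else -toward
                self.factors[inp, j] = min(hi, max(lo, self.factors[inp, j] + move))

    def reset_history(self):
        self.history.clear()

    def to_dict(self):
        d = super().to_dict()
        fb = self.feedback
        d.update(
            type="decomposable_feedback",
            feedback={
                "pos_node": fb.pos_node,
                "neg_node": fb.neg_node,
                "history_length": fb.history_length,
                "pos_deltas": np.asarray(fb.pos_deltas).tolist(),
                "neg_deltas": np.asarray(fb.neg_deltas).tolist(),
            },
        )
        return d


class LegacyFeedbackGate(Gate):
    """Non-decomposable feedback gate (comparison only, off by default).

    Reinforcement shifts the raw row entry of the remembered (input, output)
    pair by delta, moves a randomly chosen other entry of the same row the
    opposite way, clamps to [0, 1] and renormalises the row.
    """

    feedback_capable = True

    def __init__(self, input_addrs, output_addrs, rows,
                 feedback: FeedbackParams):
        super().__init__(input_addrs, output_addrs)
        rows = np.asarray(rows, dtype=float)
        self.rows = rows / rows.sum(axis=1, keepdims=True)
        GateTable(self.n_inputs, self.n_outputs, self.rows)  # validate
        self._birth_rows = self.rows.copy()
        self.feedback = feedback
        self.history: deque = deque(maxlen=feedback.history_length)

    @property
    def table(self) -> GateTable:
        return GateTable(self.n_inputs, self.n_outputs, self.rows)

    def _record(self, input_pattern, output_pattern):
        if self.feedback.history_length > 0:
            self.history.appendleft((input_pattern, output_pattern))

    def apply_feedback(self, sign: int, rng: np.random.Generator):
        if len(self.history) == 0:
            logger.debug("feedback on %s with empty history: no-op", self)
            return
        deltas = self.feedback.pos_deltas if sign > 0 else self.feedback.neg_deltas
        n_pat = 2**self.n_outputs
        for depth, (inp, out) in enumerate(self.history):
            delta = float(deltas[depth]) * (1 if sign > 0 else -1)
            others = [k for k in range(n_pat) if k != out]
            other = others[int(rng.integers(len(others)))]
            row = self.rows[inp]
            row[out] = np.clip(row[out] + delta, 0.0, 1.0)
            row[other] = np.clip(row[other] - delta, 0.0, 1.0)
            total = row.sum()
            if total <= 0:  # pathological: all mass clamped away
                row[:] = 1.0 / n_pat
            else:
                row /= total

    def reset_history(self):
        self.history.clear()

    def reset_learning(self):
        self.rows = self._birth_rows.copy()

    def to_dict(self):
        fb = self.feedback
        return {
            "type": "legacy_feedback",
            "inputs": self.input_addrs,
            "outputs": self.output_addrs,
            "rows": self.rows.tolist(),
            "feedback": {
                "pos_node": fb.pos_node,
                "neg_node": fb.neg_node,
                "history_length": fb.history_length,
                "pos_deltas": np.asarray(fb.pos_deltas).tolist(),
                "neg_deltas": np.asarray(fb.neg_deltas).tolist(),
            },
        }


def _feedback_from_dict(d: dict) -> FeedbackParams:
    return FeedbackParams(
        pos_node=int(d["pos_node"]),
        neg_node=int(d["neg_node"]),
        history_length=int(d["history_length"]),
        pos_deltas=np.asarray(d["pos_deltas"], dtype=float),
        neg_deltas=np.asarray(d["neg_deltas"], dtype=float),
    )


def gate_from_dict(d: dict) -> Gate:
    """Inverse of ``Gate.to_dict`` (JSON round-trip)."""
    kind = d["type"]
    if kind == "deterministic":
        return DeterministicGate(d["inputs"], d["outputs"], d["output_map"])
    if kind == "decomposable":
        return DecomposableGate(d["inputs"], d["outputs"], d["factors"],
                                p_min=d.get("p_min", P_MIN))
    if kind == "decomposable_feedback":
        return DecomposableFeedbackGate(
            d["inputs"], d["outputs"], d["factors"],
            _feedback_from_dict(d["feedback"]), p_min=d.get("p_min", P_MIN))
    if kind == "legacy_feedback":
        return LegacyFeedbackGate(d["inputs"], d["outputs"], d["rows"],
                                  _feedback_from_dict(d["feedback"]))
    raise ValueError(f"unknown gate type {kind!r}")
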