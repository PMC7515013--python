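"""Compiled flat-array execution engine for brains and episodes.

Evolution evaluates tens of millions of brain updates per replicate, and
the uniform-state TPM sampling for a 16-node brain needs millions more.
This module compiles a :class:`~animatphi.brain.Brain` into plain numpy
arrays and runs the synchronous update, the reinforcement rule and the
whole navigation episode inside numba-jitted kernels.  Semantics mirror the
reference Python implementation exactly (sensor persistence, OR-combining,
positive-then-negative feedback after the update, per-depth deltas); the
test suite checks agreement -- bit-exact for deterministic brains,
distributional for stochastic ones.

States are packed integers with bit ``k`` (LSB) for node ``k``.  Legacy
non-decomposable feedback gates are not supported here; they run only on
the Python path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .brain import Brain
from .environment import (ACTION_MAPPINGS, EpisodeResult, GridWorld)
from .gates import DecomposableFeedbackGate, DecomposableGate

_MAX_ARITY = 4


class EngineUnsupportedError(TypeError):
    """Raised when a brain contains gates the engine cannot compile."""


@dataclass
class CompiledBrain:
    """Flat-array image of a brain, mutated in place by the kernels."""

    n_nodes: int
    n_sensors: int
    n_motors: int
    nin: np.ndarray          # (E,)
    nout: np.ndarray         # (E,)
    in_addr: np.ndarray      # (E, 4)
    out_mask: np.ndarray     # (E, 16) node bitmask per output pattern
    rows: np.ndarray         # (E, 16, 16) current row probabilities
    is_fb: np.ndarray        # (E,) uint8
    has_factors: np.ndarray  # (E,) uint8
    factors: np.ndarray      # (E, 16, 4)
    fb_pos: np.ndarray       # (E,)
    fb_neg: np.ndarray       # (E,)
    fb_hist: np.ndarray      # (E,)
    fb_pos_d: np.ndarray     # (E, 3)
    fb_neg_d: np.ndarray     # (E, 3)
    hist_in: np.ndarray      # (E, 3)
    hist_out: np.ndarray     # (E, 3)
    hist_cnt: np.ndarray     # (E,)
    p_min: float
    birth_rows: np.ndarray
    birth_factors: np.ndarray
    state: np.ndarray        # (1,) uint64 packed node states
    agent: np.ndarray        # (4,) row, col, orientation, initialised flag

    @property
    def n_gates(self) -> int:
        return len(self.nin)

    def reset(self, scope: str = "both"):
        """Mirror of ``Brain.reset`` plus agent re-initialisation."""
        if scope in ("states", "both"):
            self.state[0] = 0
            self.hist_cnt[:] = 0
            self.agent[3] = 0
        if scope in ("learning", "both"):
            self.rows[:] = self.birth_rows
            self.factors[:] = self.birth_factors
        return self

    def writeback(self, brain: Brain):
        """Copy learned factors back into the source brain's gates."""
        for e, gate in enumerate(brain.gates):
            if isinstance(gate, DecomposableGate):
                gate.factors[:] = self.factors[e, : 2**gate.n_inputs,
                                               : gate.n_outputs]


def compile_brain(brain: Brain) -> CompiledBrain:
    E = len(brain.gates)
    nin = np.zeros(E, dtype=np.int64)
    nout = np.zeros(E, dtype=np.int64)
    in_addr = np.zeros((E, _MAX_ARITY), dtype=np.int64)
    out_mask = np.zeros((E, 2**_MAX_ARITY), dtype=np.uint64)
    rows = np.zeros((E, 2**_MAX_ARITY, 2**_MAX_ARITY), dtype=np.float64)
    is_fb = np.zeros(E, dtype=np.uint8)
    has_factors = np.zeros(E, dtype=np.uint8)
    factors = np.zeros((E, 2**_MAX_ARITY, _MAX_ARITY), dtype=np.float64)
    fb_pos = np.zeros(E, dtype=np.int64)
    fb_neg = np.zeros(E, dtype=np.int64)
    fb_hist = np.zeros(E, dtype=np.int64)
    fb_pos_d = np.zeros((E, 3), dtype=np.float64)
    fb_neg_d = np.zeros((E, 3), dtype=np.float64)
    p_min = 0.01

    sensor_mask = (1 << brain.n_sensors) - 1
    for e, gate in enumerate(brain.gates):
        if gate.feedback_capable and not isinstance(gate,
                                                    DecomposableFeedbackGate):
            raise EngineUnsupportedError(
                f"engine cannot compile {type(gate).__name__}")
        i, o = gate.n_inputs, gate.n_outputs
        nin[e], nout[e] = i, o
        in_addr[e, :i] = gate.input_addrs
        for p in range(2**o):
            mask = 0
            for j, addr in enumerate(gate.output_addrs):
                if addr < brain.n_sensors:
                    continue  # sensors are environment-owned
                if (p >> (o - 1 - j)) & 1:
                    mask |= 1 << addr
            out_mask[e, p] = mask
        rows[e, : 2**i, : 2**o] = gate.table.rows
        if isinstance(gate, DecomposableGate):
            has_factors[e] = 1
            factors[e, : 2**i, :o] = gate.factors
            p_min = gate.p_min
        if isinstance(gate, DecomposableFeedbackGate):
            is_fb[e] = 1
            fb = gate.feedback
            fb_pos[e], fb_neg[e] = fb.pos_node, fb.neg_node
            fb_hist[e] = fb.history_length
            fb_pos_d[e, : len(fb.pos_deltas[:3])] = fb.pos_deltas[:3]
            fb_neg_d[e, : len(fb.neg_deltas[:3])] = fb.neg_deltas[:3]

    return CompiledBrain(
        n_nodes=brain.n_nodes, n_sensors=brain.n_sensors,
        n_motors=brain.n_motors, nin=nin, nout=nout, in_addr=in_addr,
        out_mask=out_mask, rows=rows, is_fb=is_fb, has_factors=has_factors,
        factors=factors, fb_pos=fb_pos, fb_neg=fb_neg, fb_hist=fb_hist,
        fb_pos_d=fb_pos_d, fb_neg_d=fb_neg_d,
        hist_in=np.zeros((E, 3), dtype=np.int64),
        hist_out=np.zeros((E, 3), dtype=np.int64),
        hist_cnt=np.zeros(E, dtype=np.int64), p_min=p_min,
        birth_rows=rows.copy(), birth_factors=factors.copy(),
        state=np.zeros(1, dtype=np.uint64),
        agent=np.array([-1, -1, -1, 0], dtype=np.int64),
    )


def compile_genome(genome, n_nodes: int = 16, n_sensors: int = 4,
                   n_motors: int = 2,
                   gate_types=None, p_min: float = None,
                   delta_max: float = None) -> CompiledBrain:
    """Decode a genome straight into a :class:`CompiledBrain`.

    Functionally identical to ``compile_brain(Brain.from_genome(genome))``
    (the test suite asserts array-level equality) but avoids building gate
    objects -- evolution decodes on the order of a million genomes per run.
    Only the default gate repertoire is supported on this path.
    """
    from . import genome as gmod
    from .gates import DELTA_MAX, P_MIN

    if gate_types is None:
        gate_types = gmod.DEFAULT_GATE_TYPES
    if tuple(gate_types) != gmod.DEFAULT_GATE_TYPES:
        raise EngineUnsupportedError("fast path supports the default gate set")
    p_min = P_MIN if p_min is None else p_min
    delta_max = DELTA_MAX if delta_max is None else delta_max

    g = np.ascontiguousarray(genome, dtype=np.int64)
    positions = gmod.codon_positions(g)

    P = len(positions)
    nin = np.zeros(P, dtype=np.int64)
    nout = np.zeros(P, dtype=np.int64)
    in_addr = np.zeros((P, _MAX_ARITY), dtype=np.int64)
    out_mask = np.zeros((P, 2**_MAX_ARITY), dtype=np.uint64)
    rows = np.zeros((P, 2**_MAX_ARITY, 2**_MAX_ARITY))
    is_fb = np.zeros(P, dtype=np.uint8)
    has_factors = np.zeros(P, dtype=np.uint8)
    factors = np.zeros((P, 2**_MAX_ARITY, _MAX_ARITY))
    fb_pos = np.zeros(P, dtype=np.int64)
    fb_neg = np.zeros(P, dtype=np.int64)
    fb_hist = np.zeros(P, dtype=np.int64)
    fb_pos_d = np.zeros((P, 3))
    fb_neg_d = np.zeros((P, 3))
    E = _parse_genome_kernel(g, positions, n_nodes, n_sensors, p_min,
                             delta_max, nin, nout, in_addr, out_mask, rows,
                             is_fb, has_factors, factors, fb_pos, fb_neg,
                             fb_hist, fb_pos_d, fb_neg_d) if P else 0
    return CompiledBrain(
        n_nodes=n_nodes, n_sensors=n_sensors, n_motors=n_motors,
        nin=nin[:E], nout=nout[:E], in_addr=in_addr[:E],
        out_mask=out_mask[:E], rows=rows[:E], is_fb=is_fb[:E],
        has_factors=has_factors[:E], factors=factors[:E],
        fb_pos=fb_pos[:E], fb_neg=fb_neg[:E], fb_hist=fb_hist[:E],
        fb_pos_d=fb_pos_d[:E], fb_neg_d=fb_neg_d[:E],
        hist_in=np.zeros((E, 3), dtype=np.int64),
        hist_out=np.zeros((E, 3), dtype=np.int64),
        hist_cnt=np.zeros(E, dtype=np.int64), p_min=p_min,
        birth_rows=rows[:E].copy(), birth_factors=factors[:E].copy(),
        state=np.zeros(1, dtype=np.uint64),
        agent=np.array([-1, -1, -1, 0], dtype=np.int64),
    )


# -- kernels --------------------------------------------------------------

@njit(cache=True)
def _parse_genome_kernel(g, positions, n_nodes, n_sensors, p_min, delta_max,
                         nin, nout, in_addr, out_mask, rows, is_fb,
                         has_factors, factors, fb_pos, fb_neg, fb_hist,
                         fb_pos_d, fb_neg_d):
    """Gene parser (hot path of evolution); mirrors ``genome._decode_gene``
    for the default gate repertoire.  Returns the number of decoded gates."""
    L = g.shape[0]
    E = 0
    for t in range(positions.shape[0]):
        p = positions[t] + 2
        if p + 3 > L:
            continue
        kind = g[p] % 3
        i = 1 + g[p + 1] % 4
        o = 1 + g[p + 2] % 4
        a0 = p + 3
        p2 = a0 + i + o
        if kind == 0:
            need = 1 << i
        elif kind == 1:
            need = (1 << i) * o
        else:
            need = (1 << i) * o + 9
        if p2 + need > L:
            continue
        e = E
        E += 1
        nin[e] = i
        nout[e] = o
        for j in range(i):
            in_addr[e, j] = g[a0 + j] % n_nodes
        for pat in range(1 << o):
            m = np.uint64(0)
            for j in range(o):
                addr = g[a0 + i + j] % n_nodes
                if addr >= n_sensors and ((pat >> (o - 1 - j)) & 1) == 1:
                    m |= np.uint64(1) << np.uint64(addr)
            out_mask[e, pat] = m
        if kind == 0:
            for r in range(1 << i):
                rows[e, r, g[p2 + r] % (1 << o)] = 1.0
        else:
            has_factors[e] = 1
            for r in range(1 << i):
                for j in range(o):
                    v = g[p2 + r * o + j] / 255.0
                    if v < p_min:
                        v = p_min
                    elif v > 1.0 - p_min:
                        v = 1.0 - p_min
                    factors[e, r, j] = v
                for pat in range(1 << o):
                    prod = 1.0
                    for j in range(o):
                        if ((pat >> (o - 1 - j)) & 1) == 1:
                            prod *= factors[e, r, j]
                        else:
                            prod *= 1.0 - factors[e, r, j]
                    rows[e, r, pat] = prod
            if kind == 2:
                q = p2 + (1 << i) * o
                is_fb[e] = 1
                fb_pos[e] = g[q] % n_nodes
                fb_neg[e] = g[q + 1] % n_nodes
                fb_hist[e] = g[q + 2] % 4
                for j in range(3):
                    fb_pos_d[e, j] = g[q + 3 + j] / 255.0 * delta_max
                    fb_neg_d[e, j] = g[q + 6 + j] / 255.0 * delta_max
    return E


@njit(cache=True, inline="always")
def _sample_row(row, npat, rng):
    r = rng.random()
    acc = 0.0
    for p in range(npat):
        acc += row[p]
        if r < acc:
            return p
    return npat - 1


@njit(cache=True)
def _apply_feedback(e, sign, nout, rows, factors, fb_pos_d, fb_neg_d,
                    hist_in, hist_out, hist_cnt, p_min):
    o = nout[e]
    lo, hi = p_min, 1.0 - p_min
    for depth in range(hist_cnt[e]):
        delta = fb_pos_d[e, depth] if sign > 0 else fb_neg_d[e, depth]
        inp = hist_in[e, depth]
        out = hist_out[e, depth]
        for j in range(o):
            bit = (out >> (o - 1 - j)) & 1
            toward = delta if bit == 1 else -delta
            move = toward if sign > 0 else -toward
            f = factors[e, inp, j] + move
            if f < lo:
                f = lo
            elif f > hi:
                f = hi
            factors[e, inp, j] = f
        npat = 1 << o
        for p in range(npat):
            prod = 1.0
            for j in range(o):
                bit = (p >> (o - 1 - j)) & 1
                prod *= factors[e, inp, j] if bit == 1 else 1.0 - factors[e, inp, j]
            rows[e, inp, p] = prod


@njit(cache=True)
def _step_state(state, learning, n_sensors,
                nin, nout, in_addr, out_mask, rows,
                is_fb, fb_pos, fb_neg, fb_hist, fb_pos_d, fb_neg_d,
                hist_in, hist_out, hist_cnt, factors, p_min, rng):
    """One synchronous brain update from packed ``state``; returns the new
    packed state.  Mutates histories, and (when learning) rows/factors."""
    E = nin.shape[0]
    sensor_mask = np.uint64((1 << n_sensors) - 1)
    new = np.uint64(state) & sensor_mask
    for e in range(E):
        idx = 0
        for j in range(nin[e]):
            idx = (idx << 1) | int((np.uint64(state) >> np.uint64(in_addr[e, j])) & np.uint64(1))
        out = _sample_row(rows[e, idx], 1 << nout[e], rng)
        new |= out_mask[e, out]
        if is_fb[e] == 1 and fb_hist[e] > 0:
            cnt = hist_cnt[e] + 1
            if cnt > fb_hist[e]:
                cnt = fb_hist[e]
            for s in range(cnt - 1, 0, -1):
                hist_in[e, s] = hist_in[e, s - 1]
                hist_out[e, s] = hist_out[e, s - 1]
            hist_in[e, 0] = idx
            hist_out[e, 0] = out
            hist_cnt[e] = cnt
    if learning:
        for e in range(E):
            if is_fb[e] == 1:
                if (new >> np.uint64(fb_pos[e])) & np.uint64(1):
                    _apply_feedback(e, 1, nout, rows, factors, fb_pos_d,
                                    fb_neg_d, hist_in, hist_out, hist_cnt,
                                    p_min)
                if (new >> np.uint64(fb_neg[e])) & np.uint64(1):
                    _apply_feedback(e, -1, nout, rows, factors, fb_pos_d,
                                    fb_neg_d, hist_in, hist_out, hist_cnt,
                                    p_min)
    return new


@njit(cache=True)
def _step_state_pure(state, n_nodes, n_sensors, nin, nout, in_addr, out_mask,
                     rows, rng):
    """Measurement-only update: no learning, no history (for TPM sampling)."""
    E = nin.shape[0]
    sensor_mask = np.uint64((1 << n_sensors) - 1)
    new = np.uint64(state) & sensor_mask
    for e in range(E):
        idx = 0
        for j in range(nin[e]):
            idx = (idx << 1) | int((np.uint64(state) >> np.uint64(in_addr[e, j])) & np.uint64(1))
        out = _sample_row(rows[e, idx], 1 << nout[e], rng)
        new |= out_mask[e, out]
    return new


@njit(cache=True)
def _spawn(spawn_r, spawn_c, arrows, face_arrow, agent, rng):
    k = int(rng.random() * len(spawn_r))
    if k >= len(spawn_r):
        k = len(spawn_r) - 1
    agent[0] = spawn_r[k]
    agent[1] = spawn_c[k]
    if face_arrow:
        agent[2] = arrows[agent[0], agent[1]]
    else:
        agent[2] = int(rng.random() * 4) % 4
    agent[3] = 1


@njit(cache=True)
def _episode_kernel(walls, arrows, goal_r, goal_c, spawn_r, spawn_c,
                    face_arrow, mapping, n_steps, learning,
                    n_sensors, n_motors,
                    nin, nout, in_addr, out_mask, rows,
                    is_fb, fb_pos, fb_neg, fb_hist, fb_pos_d, fb_neg_d,
                    hist_in, hist_out, hist_cnt, factors, p_min,
                    state, agent, trace, counts, rng):
    """Run ``n_steps`` of the navigation episode; returns goals reached.

    ``state``/``agent`` persist across calls so a caller can pause the
    episode at checkpoints.  Result codes: 0 idle, 1 forward, 2 left,
    3 right.  Sensor bits: 0 idle, 1 right, 2 forward, 3 left.
    """
    dr = (-1, 0, 1, 0)
    dc = (0, 1, 0, -1)
    if agent[3] == 0:
        _spawn(spawn_r, spawn_c, arrows, face_arrow, agent, rng)
    goals = 0
    record = trace.shape[0] > 0
    for t in range(n_steps):
        # sensor encoding of the arrow under the animat
        arrow = arrows[agent[0], agent[1]]
        s = np.uint64(state[0]) & ~np.uint64(15)
        if arrow < 0:
            s |= np.uint64(1)  # idle percept
        else:
            rel = (arrow - agent[2]) % 4
            if rel == 0:
                s |= np.uint64(4)  # forward
            elif rel == 3:
                s |= np.uint64(8)  # left
            else:
                s |= np.uint64(2)  # right (incl. 180-degree case)
        if record:
            trace[t] = np.uint32(s)
        new = _step_state(s, learning, n_sensors, nin, nout, in_addr,
                          out_mask, rows, is_fb, fb_pos, fb_neg, fb_hist,
                          fb_pos_d, fb_neg_d, hist_in, hist_out, hist_cnt,
                          factors, p_min, rng)
        state[0] = new
        action = int((new >> np.uint64(n_sensors)) & np.uint64(1)) * 2 + \
            int((new >> np.uint64(n_sensors + 1)) & np.uint64(1))
        result = mapping[action]
        counts[result] += 1
        if result == 2:    # left turn
            agent[2] = (agent[2] - 1) % 4
        elif result == 3:  # right turn
            agent[2] = (agent[2] + 1) % 4
        elif result == 1:  # forward
            rr = agent[0] + dr[agent[2]]
            cc = agent[1] + dc[agent[2]]
            if walls[rr, cc] == 0:
                agent[0] = rr
                agent[1] = cc
        if agent[0] == goal_r and agent[1] == goal_c:
            goals += 1
            _spawn(spawn_r, spawn_c, arrows, face_arrow, agent, rng)
    return goals


@njit(cache=True)
def _evaluate_mappings_kernel(walls, arrows, goal_r, goal_c, spawn_r, spawn_c,
                              face_arrow, mappings, lifetime, learning,
                              n_sensors, n_motors,
                              nin, nout, in_addr, out_mask, rows,
                              is_fb, fb_pos, fb_neg, fb_hist, fb_pos_d,
                              fb_neg_d, hist_in, hist_out, hist_cnt, factors,
                              p_min, birth_rows, birth_factors,
                              state, agent, counts, goals_out, rng):
    """All mapping variants in one call, resetting the brain to its naive
    (birth) tables and cleared state before each."""
    trace = np.zeros(0, dtype=np.uint32)
    for m in range(mappings.shape[0]):
        rows[:, :, :] = birth_rows
        factors[:, :, :] = birth_factors
        hist_cnt[:] = 0
        state[0] = np.uint64(0)
        agent[3] = 0
        goals_out[m] = _episode_kernel(
            walls, arrows, goal_r, goal_c, spawn_r, spawn_c, face_arrow,
            mappings[m], lifetime, learning, n_sensors, n_motors,
            nin, nout, in_addr, out_mask, rows, is_fb, fb_pos, fb_neg,
            fb_hist, fb_pos_d, fb_neg_d, hist_in, hist_out, hist_cnt,
            factors, p_min, state, agent, trace, counts[m], rng)


@njit(cache=True)
def _sample_transitions_kernel(n_nodes, n_sensors, k, nin, nout, in_addr,
                               out_mask, rows, rng, out):
    for s in range(1 << n_nodes):
        base = s * k
        for rep in range(k):
            out[base + rep] = np.uint32(
                _step_state_pure(np.uint64(s), n_nodes, n_sensors, nin, nout,
                                 in_addr, out_mask, rows, rng))


# -- wrappers -------------------------------------------------------------

def _world_arrays(world: GridWorld):
    """Cached uint8 wall mask for kernel calls."""
    cached = getattr(world, "_walls_u8", None)
    if cached is None:
        cached = np.ascontiguousarray(world.walls, dtype=np.uint8)
        world._walls_u8 = cached
    return (cached,)


def run_episode_compiled(cb: CompiledBrain, world: GridWorld, mapping,
                         rng: np.random.Generator, lifetime: int = 512,
                         learning_enabled: bool = True,
                         record_trace: bool = False,
                         face_arrow_on_spawn: bool = False,
                         mapping_index: int | None = None) -> EpisodeResult:
    """Engine counterpart of :func:`animatphi.environment.run_episode`."""
    if cb.n_sensors != 4 or cb.n_motors != 2:
        raise EngineUnsupportedError(
            "episode kernel expects the 4-sensor / 2-motor task layout")
    trace = np.zeros(lifetime if record_trace else 0, dtype=np.uint32)
    counts = np.zeros(4, dtype=np.int64)
    mapping_arr = np.asarray([int(r) for r in mapping], dtype=np.int64)
    goals = _episode_kernel(
        _world_arrays(world)[0], world.arrows,
        world.goal[0], world.goal[1],
        world.spawn_cells[:, 0], world.spawn_cells[:, 1],
        face_arrow_on_spawn, mapping_arr, lifetime, learning_enabled,
        cb.n_sensors, cb.n_motors,
        cb.nin, cb.nout, cb.in_addr, cb.out_mask, cb.rows,
        cb.is_fb, cb.fb_pos, cb.fb_neg, cb.fb_hist, cb.fb_pos_d, cb.fb_neg_d,
        cb.hist_in, cb.hist_out, cb.hist_cnt, cb.factors, cb.p_min,
        cb.state, cb.agent, trace, counts, rng)
    return EpisodeResult(goals_reached=int(goals), action_counts=counts,
                         state_trace=trace if record_trace else None,
                         mapping_index=mapping_index)


def evaluate_all_mappings_compiled(cb: CompiledBrain, world: GridWorld,
                                   rng: np.random.Generator,
                                   lifetime: int = 512, mapping_indices=None,
                                   learning_enabled: bool = True,
                                   record_trace: bool = False,
                                   face_arrow_on_spawn: bool = False):
    """Total goals over mapping variants, brain reset naive before each."""
    if mapping_indices is None:
        mapping_indices = range(len(ACTION_MAPPINGS))
    mapping_indices = list(mapping_indices)
    if not record_trace:  # fused fast path used by evolution
        if cb.n_sensors != 4 or cb.n_motors != 2:
            raise EngineUnsupportedError(
                "episode kernel expects the 4-sensor / 2-motor task layout")
        M = len(mapping_indices)
        mappings = np.array([[int(r) for r in ACTION_MAPPINGS[m]]
                             for m in mapping_indices], dtype=np.int64)
        counts = np.zeros((M, 4), dtype=np.int64)
        goals = np.zeros(M, dtype=np.int64)
        _evaluate_mappings_kernel(
            _world_arrays(world)[0], world.arrows,
            world.goal[0], world.goal[1],
            world.spawn_cells[:, 0], world.spawn_cells[:, 1],
            face_arrow_on_spawn, mappings, lifetime, learning_enabled,
            cb.n_sensors, cb.n_motors, cb.nin, cb.nout, cb.in_addr,
            cb.out_mask, cb.rows, cb.is_fb, cb.fb_pos, cb.fb_neg, cb.fb_hist,
            cb.fb_pos_d, cb.fb_neg_d, cb.hist_in, cb.hist_out, cb.hist_cnt,
            cb.factors, cb.p_min, cb.birth_rows, cb.birth_factors,
            cb.state, cb.agent, counts, goals, rng)
        results = [EpisodeResult(goals_reached=int(goals[k]),
                                 action_counts=counts[k], state_trace=None,
                                 mapping_index=m)
                   for k, m in enumerate(mapping_indices)]
        return int(goals.sum()), results
    total = 0
    results = []
    for m in mapping_indices:
        cb.reset("both")
        res = run_episode_compiled(cb, world, ACTION_MAPPINGS[m], rng,
                                   lifetime=lifetime,
                                   learning_enabled=learning_enabled,
                                   record_trace=record_trace,
                                   face_arrow_on_spawn=face_arrow_on_spawn,
                                   mapping_index=m)
        total += res.goals_reached
        results.append(res)
    return total, results


def sample_transitions(brain_or_cb, samples_per_state: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Sampled next states, ``samples_per_state`` per start state, as a flat
    uint32 array ordered state-major (for TPM estimation at large n)."""
    cb = brain_or_cb if isinstance(brain_or_cb, CompiledBrain) \
        else compile_brain(brain_or_cb)
    n = cb.n_nodes
    out = np.zeros((1 << n) * samples_per_state, dtype=np.uint32)
    _sample_transitions_kernel(n, cb.n_sensors, samples_per_state, cb.nin,
                               cb.nout, cb.in_addr, cb.out_mask, cb.rows,
                               rng, out)
    return out
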