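"""Integrated-information measures for Markov Brains.

The atomic-partition integrated information of a system of binary nodes
X = (X^(1), ..., X^(n)) observed across one time step is

    Phi_atomic = sum_i H(X_t^(i) | X_{t+1}^(i))  -  H(X_t | X_{t+1})

equivalently (the algebraic identity the test suite verifies numerically)

    Phi_atomic = I(X_t : X_{t+1}) - sum_i I(X_t^(i) : X_{t+1}^(i)) + Ibar,
    Ibar       = sum_i H(X_t^(i)) - H(X_t),

i.e. the information the whole system carries across the step beyond the
sum carried by its nodes individually, corrected by the spatial
nonindependence Ibar.  All logs are base 2; 0 log 0 = 0; Phi is in bits.

Two ways of obtaining the required joint distribution p(x_t, x_{t+1}):

* from a recorded **state trace** of a behaving animat (plug-in empirical
  distribution over consecutive state pairs), the classical protocol;
* from a **transition probability matrix** (TPM) of the frozen brain at one
  instant, combined with a chosen current-state distribution.  With the
  maximum-entropy (uniform) state distribution this yields **PhiMaxH**,
  which is measurable at any point of the animat's life -- before, during
  and after learning -- without observing behaviour.  A brain whose tables
  do not change during its lifetime has the same TPM at every time point,
  so its PhiMaxH trajectory is exactly flat.

TPMs are built analytically (exact enumeration of the joint gate-outcome
space) when the state space is small enough, and by stochastic sampling of
brain updates otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .brain import Brain
from .config import PhiConfig
from .engine import EngineUnsupportedError, sample_transitions
from .environment import GridWorld, run_episode
from .gates import Gate, GateTable

_LOG2 = np.log(2.0)


def _entropy_bits(weights: np.ndarray) -> float:
    """Shannon entropy of (possibly unnormalised) non-negative weights."""
    total = weights.sum()
    if total <= 0:
        return 0.0
    p = weights / total
    return float(-xlogy(p, p).sum() / _LOG2)


@dataclass
class TPM:
    """State-to-state transition probability matrix of a frozen brain."""

    n_nodes: int
    matrix: np.ndarray            # (2^n, 2^n), row-stochastic
    construction: str = "analytic"  # "analytic" | "sampled(k=..., seed=...)"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        size = 2**self.n_nodes
        if self.matrix.shape != (size, size):
            raise ValueError(f"TPM must be {size}x{size}")
        sums = self.matrix.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-6:
            raise ValueError("TPM rows must sum to 1")


def uniform_state_distribution(n_nodes: int) -> np.ndarray:
    """The maximum-entropy current-state distribution H_t."""
    return np.full(2**n_nodes, 1.0 / 2**n_nodes)


@dataclass
class PhiResult:
    """Phi_atomic and its entropy components (all in bits)."""

    phi_atomic: float
    i_sys: float                  # I(X_t : X_{t+1})
    per_node_i: np.ndarray        # I(X_t^(i) : X_{t+1}^(i))
    nonindependence: float        # Ibar
    per_node_cond_h: np.ndarray   # H(X_t^(i) | X_{t+1}^(i))
    joint_cond_h: float           # H(X_t | X_{t+1})
    n_nodes: int = 0

    @property
    def phi_mi_assembly(self) -> float:
        """The mutual-information assembly of the same quantity."""
        return float(self.i_sys - self.per_node_i.sum() + self.nonindependence)

    def to_dict(self) -> dict:
        return {
            "phi_atomic": self.phi_atomic,
            "i_sys": self.i_sys,
            "per_node_i": self.per_node_i.tolist(),
            "nonindependence": self.nonindependence,
            "per_node_cond_h": self.per_node_cond_h.tolist(),
            "joint_cond_h": self.joint_cond_h,
            "n_nodes": self.n_nodes,
        }


def _phi_from_pairs(xt: np.ndarray, xt1: np.ndarray, weights: np.ndarray,
                    n_nodes: int) -> PhiResult:
    """Phi components from a weighted list of (x_t, x_{t+1}) state pairs.

    Handles dense-TPM supports, sampled transitions and empirical traces
    alike; duplicate pairs are merged before entropies are taken.
    """
    xt = np.asarray(xt, dtype=np.int64)
    xt1 = np.asarray(xt1, dtype=np.int64)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    keys = xt << np.int64(n_nodes) | xt1
    uniq, inv = np.unique(keys, return_inverse=True)
    pw = np.bincount(inv, weights=w)
    h_joint = _entropy_bits(pw)

    size = 2**n_nodes
    pt = np.bincount(xt, weights=w, minlength=size)
    pt1 = np.bincount(xt1, weights=w, minlength=size)
    h_t = _entropy_bits(pt)
    h_t1 = _entropy_bits(pt1)

    per_node_i = np.zeros(n_nodes)
    per_node_cond_h = np.zeros(n_nodes)
    h_t_nodes = np.zeros(n_nodes)
    for i in range(n_nodes):
        bt = (xt >> i) & 1
        bt1 = (xt1 >> i) & 1
        joint2 = np.bincount(bt * 2 + bt1, weights=w, minlength=4)
        hb_joint = _entropy_bits(joint2)
        hb_t = _entropy_bits(joint2.reshape(2, 2).sum(axis=1))
        hb_t1 = _entropy_bits(joint2.reshape(2, 2).sum(axis=0))
        h_t_nodes[i] = hb_t
        per_node_i[i] = hb_t + hb_t1 - hb_joint
        per_node_cond_h[i] = hb_joint - hb_t1

    joint_cond_h = h_joint - h_t1
    return PhiResult(
        phi_atomic=float(per_node_cond_h.sum() - joint_cond_h),
        i_sys=float(h_t + h_t1 - h_joint),
        per_node_i=per_node_i,
        nonindependence=float(h_t_nodes.sum() - h_t),
        per_node_cond_h=per_node_cond_h,
        joint_cond_h=float(joint_cond_h),
        n_nodes=n_nodes,
    )


# -- TPM construction -----------------------------------------------------

def _total_output_bits(brain: Brain) -> int:
    return sum(g.n_outputs for g in brain.gates)


def analytic_feasible(brain: Brain, config: PhiConfig | None = None) -> bool:
    config = config or PhiConfig()
    return (brain.n_nodes <= config.analytic_max_nodes
            and _total_output_bits(brain) <= config.analytic_max_output_bits)


def analytic_tpm(brain: Brain, config: PhiConfig | None = None) -> TPM:
    """Exact TPM by enumerating, per start state, the joint outcome space of
    all gates (gates fire independently; outputs OR-combine; unwritten
    motor/hidden nodes decay to 0; sensors self-copy)."""
    if not analytic_feasible(brain, config):
        raise ValueError(
            "state space too large for exact enumeration; use sampled_tpm "
            "or phi_maxh (which falls back to sampling)")
    n = brain.n_nodes
    size = 2**n
    sensor_mask = (1 << brain.n_sensors) - 1

    # precompute per gate: rows and output-pattern -> node-bitmask
    gate_rows = []
    gate_masks = []
    for gate in brain.gates:
        gate_rows.append(gate.table.rows)
        o = gate.n_outputs
        masks = np.zeros(2**o, dtype=np.int64)
        for p in range(2**o):
            m = 0
            for j, addr in enumerate(gate.output_addrs):
                if addr < brain.n_sensors:
                    continue
                if (p >> (o - 1 - j)) & 1:
                    m |= 1 << addr
            masks[p] = m
        gate_masks.append(masks)

    matrix = np.zeros((size, size))
    for s in range(size):
        dist = {s & sensor_mask: 1.0}
        for gate, rows, masks in zip(brain.gates, gate_rows, gate_masks):
            idx = 0
            for addr in gate.input_addrs:
                idx = (idx << 1) | ((s >> addr) & 1)
            row = rows[idx]
            new = {}
            for partial, pprob in dist.items():
                for p, prob in enumerate(row):
                    if prob == 0.0:
                        continue
                    key = partial | int(masks[p])
                    new[key] = new.get(key, 0.0) + pprob * prob
            dist = new
        for nxt, prob in dist.items():
            matrix[s, nxt] = prob
    return TPM(n_nodes=n, matrix=matrix, construction="analytic")


def sampled_tpm(brain: Brain, samples_per_state: int,
                rng: np.random.Generator, max_nodes: int = 12) -> TPM:
    """TPM estimated by stochastic sampling: ``samples_per_state`` brain
    updates from every start state, learning disabled during measurement.
    The estimator converges to :func:`analytic_tpm` at rate O(k^-1/2)."""
    if samples_per_state < 1:
        raise ValueError("samples_per_state must be >= 1")
    n = brain.n_nodes
    if n > max_nodes:
        raise ValueError("dense sampled TPM limited to small node counts; "
                         "use phi_maxh for large brains")
    size = 2**n
    try:
        nxt = sample_transitions(brain, samples_per_state, rng)
        counts = np.zeros((size, size))
        rows_idx = np.repeat(np.arange(size), samples_per_state)
        np.add.at(counts, (rows_idx, nxt.astype(np.int64)), 1.0)
    except EngineUnsupportedError:  # legacy gates: slow reference path
        measured = brain.snapshot().reset("states")
        counts = np.zeros((size, size))
        for s in range(size):
            for _ in range(samples_per_state):
                counts[s, measured.next_state_free(s, rng)] += 1.0
    return TPM(n_nodes=n, matrix=counts / samples_per_state,
               construction=f"sampled(k={samples_per_state})")


# -- Phi entry points -----------------------------------------------------

def phi_atomic_from_tpm(tpm: TPM, input_dist: np.ndarray | None = None
                        ) -> PhiResult:
    """Phi_atomic of a TPM under ``input_dist`` (uniform when omitted --
    the PhiMaxH construction)."""
    n = tpm.n_nodes
    p = uniform_state_distribution(n) if input_dist is None \
        else np.asarray(input_dist, dtype=float)
    if p.shape != (2**n,) or abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("input_dist must be a distribution over 2^n states")
    joint = p[:, None] * tpm.matrix
    xt, xt1 = np.nonzero(joint)
    return _phi_from_pairs(xt, xt1, joint[xt, xt1], n)


def phi_atomic_eq3(tpm: TPM, input_dist: np.ndarray | None = None
                   ) -> PhiResult:
    """Independent assembly of the same quantity from mutual informations
    and the nonindependence term, computed with its own explicit sums (the
    permanent numerical cross-check of :func:`phi_atomic_from_tpm`)."""
    n = tpm.n_nodes
    size = 2**n
    p = uniform_state_distribution(n) if input_dist is None \
        else np.asarray(input_dist, dtype=float)
    joint = p[:, None] * tpm.matrix          # p(x_t, x_{t+1})
    pt = joint.sum(axis=1)
    pt1 = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / np.outer(pt, pt1)
        i_sys = float(np.nansum(xlogy(joint, np.where(joint > 0, ratio, 1.0)))
                      / _LOG2)

    bits = (np.arange(size)[:, None] >> np.arange(n)[None, :]) & 1
    per_node_i = np.zeros(n)
    h_nodes_t = np.zeros(n)
    per_node_cond_h = np.zeros(n)
    for i in range(n):
        j2 = np.zeros((2, 2))
        for a in range(2):
            for b in range(2):
                sel = np.outer(bits[:, i] == a, bits[:, i] == b)
                j2[a, b] = joint[sel].sum()
        ma, mb = j2.sum(axis=1), j2.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = j2 / np.outer(ma, mb)
            per_node_i[i] = float(
                np.nansum(xlogy(j2, np.where(j2 > 0, r2, 1.0))) / _LOG2)
        h_nodes_t[i] = _entropy_bits(ma)
        per_node_cond_h[i] = _entropy_bits(j2.ravel()) - _entropy_bits(mb)

    nonind = float(h_nodes_t.sum() - _entropy_bits(pt))
    phi = i_sys - per_node_i.sum() + nonind
    joint_cond_h = _entropy_bits(joint.ravel()) - _entropy_bits(pt1)
    return PhiResult(phi_atomic=float(phi), i_sys=i_sys,
                     per_node_i=per_node_i, nonindependence=nonind,
                     per_node_cond_h=per_node_cond_h,
                     joint_cond_h=float(joint_cond_h), n_nodes=n)


def phi_atomic_from_pairs(xt, xt1, n_nodes: int,
                          weights=None) -> PhiResult:
    """Plug-in Phi_atomic from explicit (x_t, x_{t+1}) transition pairs,
    e.g. transitions sampled independently at uniform stationarity."""
    xt = np.asarray(xt, dtype=np.int64)
    if weights is None:
        weights = np.full(xt.size, 1.0 / xt.size)
    return _phi_from_pairs(xt, xt1, weights, n_nodes)


def phi_atomic_from_trace(state_trace, n_nodes: int) -> PhiResult:
    """Plug-in Phi_atomic from a recorded trace of packed brain states."""
    trace = np.asarray(state_trace, dtype=np.int64)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("state trace must contain at least two time points")
    xt, xt1 = trace[:-1], trace[1:]
    return _phi_from_pairs(xt, xt1, np.full(xt.size, 1.0 / xt.size), n_nodes)


# -- PhiMaxH and lifetime trajectories ------------------------------------

def _restrict_nonsensor(brain: Brain) -> Brain:
    """View of the brain on its non-sensor nodes only: sensor inputs are
    clamped to 0, outputs aimed at sensors are dropped, addresses shift
    down by ``n_sensors``.  Learned tables are carried over frozen."""
    ns = brain.n_sensors
    if ns == 0:
        return brain
    gates = []
    for gate in brain.gates:
        keep_in = [j for j, a in enumerate(gate.input_addrs) if a >= ns]
        keep_out = [j for j, a in enumerate(gate.output_addrs) if a >= ns]
        if not keep_out:
            continue
        rows = gate.table.rows
        i, o = gate.n_inputs, gate.n_outputs
        # select rows where clamped (sensor) input bits are 0
        sel = [r for r in range(2**i)
               if all((r >> (i - 1 - j)) & 1 == 0
                      for j in range(i) if j not in keep_in)]
        rows = rows[sel]
        # marginalise dropped output bits
        if len(keep_out) < o:
            new_rows = np.zeros((rows.shape[0], 2**len(keep_out)))
            for pat in range(2**o):
                sub = 0
                for k, j in enumerate(keep_out):
                    sub |= ((pat >> (o - 1 - j)) & 1) << (len(keep_out) - 1 - k)
                new_rows[:, sub] += rows[:, pat]
            rows = new_rows
        in_addrs = [gate.input_addrs[j] - ns for j in keep_in] or [0]
        if not keep_in:
            rows = np.vstack([rows, rows])  # dummy input, both values alike
        out_addrs = [gate.output_addrs[j] - ns for j in keep_out]
        gates.append(_TableGate(in_addrs, out_addrs, rows))
    return Brain(gates, n_nodes=brain.n_nodes - ns, n_sensors=0,
                 n_motors=brain.n_motors, learning_enabled=False)


class _TableGate(Gate):
    """Internal gate defined directly by a row-stochastic table (used for
    node-set restricted TPM views)."""

    def __init__(self, input_addrs, output_addrs, rows):
        super().__init__(input_addrs, output_addrs)
        self.rows = np.asarray(rows, dtype=float)
        GateTable(self.n_inputs, self.n_outputs, self.rows)

    @property
    def table(self) -> GateTable:
        return GateTable(self.n_inputs, self.n_outputs, self.rows)

    def to_dict(self):
        return {"type": "table", "inputs": self.input_addrs,
                "outputs": self.output_addrs, "rows": self.rows.tolist()}


def phi_maxh_result(brain: Brain, config: PhiConfig | None = None,
                    rng: np.random.Generator | None = None) -> PhiResult:
    """PhiMaxH of a brain at one instant, with all entropy components:
    Phi_atomic of its current TPM under the uniform (maximum-entropy) state
    distribution.

    Exact TPM when the state space allows it, otherwise stochastic sampling
    with ``config.samples_per_state`` draws per start state.  Changing the
    node set (``config.node_set``) is an explicit configuration choice.
    """
    config = config or PhiConfig()
    target = brain
    if config.node_set == "exclude_sensors":
        target = _restrict_nonsensor(brain)
    elif config.node_set != "all":
        raise ValueError(f"unknown node_set {config.node_set!r}")

    if analytic_feasible(target, config):
        return phi_atomic_from_tpm(analytic_tpm(target, config))

    rng = np.random.default_rng() if rng is None else rng
    k = config.samples_per_state
    frozen = target.snapshot().reset("states")
    nxt = sample_transitions(frozen, k, rng).astype(np.int64)
    n = target.n_nodes
    xt = np.repeat(np.arange(2**n, dtype=np.int64), k)
    return _phi_from_pairs(xt, nxt, np.full(nxt.size, 1.0 / nxt.size), n)


def phi_maxh(brain: Brain, config: PhiConfig | None = None,
             rng: np.random.Generator | None = None) -> float:
    """Scalar convenience wrapper around :func:`phi_maxh_result`."""
    return phi_maxh_result(brain, config, rng).phi_atomic


@dataclass
class PhiTrajectory:
    """PhiMaxH sampled along one lifetime, with its linear-trend proxy."""

    timesteps: np.ndarray
    phi_values: np.ndarray
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return {"timesteps": self.timesteps.tolist(),
                "phi_values": self.phi_values.tolist(),
                "slope": self.slope, "intercept": self.intercept}


def phi_maxh_trajectory(brain: Brain, world: GridWorld, mapping,
                        rng: np.random.Generator, lifetime: int = 512,
                        config: PhiConfig | None = None) -> PhiTrajectory:
    """Run one learning episode, snapshotting the gate tables every
    ``config.checkpoint_stride`` timesteps (including birth, t = 0), and
    measure PhiMaxH at each snapshot.  The ordinary-least-squares slope of
    PhiMaxH against time is the lifetime-change proxy.  A brain without
    feedback gates yields an exactly flat trajectory."""
    config = config or PhiConfig()
    brain.reset("both")
    result = run_episode(brain, world, mapping, rng, lifetime=lifetime,
                         checkpoint_stride=config.checkpoint_stride,
                         record_trace=False)
    times = np.array([t for t, _ in result.checkpoints], dtype=float)
    values = np.array([phi_maxh(snap, config, rng)
                       for _, snap in result.checkpoints])
    slope, intercept = np.polyfit(times, values, 1) if len(times) > 1 \
        else (0.0, float(values[0]))
    return PhiTrajectory(timesteps=times, phi_values=values,
                         slope=float(slope), intercept=float(intercept))


# -- TPM I/O ---------------------------------------------------------------

def tpm_to_files(tpm: TPM, csv_path, meta_path):
    """Dense matrix as CSV plus a JSON sidecar with n and construction."""
    np.savetxt(csv_path, tpm.matrix, delimiter=",")
    with open(meta_path, "w") as fh:
        json.dump({"n_nodes": tpm.n_nodes, "construction": tpm.construction},
                  fh)


def tpm_from_files(csv_path, meta_path) -> TPM:
    with open(meta_path) as fh:
        meta = json.load(fh)
    matrix = np.loadtxt(csv_path, delimiter=",")
    return TPM(n_nodes=meta["n_nodes"], matrix=matrix,
               construction=meta["construction"])
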