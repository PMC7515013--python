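"""Deterministic toy brains and worlds with known closed-form properties.

These constructions anchor the test suite and the worked examples:

* ``copy_brain`` -- two independent identity nodes; the parts carry exactly
  the information of the whole, so Phi_atomic = 0 bits.
* ``swap_brain`` -- two nodes exchanging their states each step; each node's
  next value tells nothing about its own past (1 bit of conditional entropy
  per node) while the whole map is invertible, so Phi_atomic = 2 bits.
* ``xor_brain`` -- both next nodes equal x XOR y; Phi_atomic = 1 bit.
* ``coin_brain`` -- a single fair-coin node (maximally noisy 1-node TPM).
* ``feedback_probe_brain`` -- one decomposable feedback gate whose
  reinforcement nodes are sensors, so a test (or environment) can inject
  positive/negative feedback directly.
* ``corridor_world`` -- a straight corridor whose arrows all say "forward";
  an oracle that knows the action mapping scores exactly
  lifetime / spawn_distance goals per episode.
* ``open_world_5x5`` -- the smallest open arena with the goal at the centre
  (hand-checkable distance and arrow fields).
"""

from __future__ import annotations

import numpy as np

from .brain import Brain
from .environment import GridWorld, world_from_text
from .gates import (DecomposableFeedbackGate, DecomposableGate,
                    DeterministicGate, FeedbackParams)

FIXTURE_NAMES = ("copy_brain", "swap_brain", "xor_brain", "coin_brain",
                 "feedback_probe_brain", "corridor_world", "open_world_5x5")


def _copy_brain() -> Brain:
    return Brain([DeterministicGate([0], [0], [0, 1]),
                  DeterministicGate([1], [1], [0, 1])],
                 n_nodes=2, n_sensors=0, n_motors=0)


def _swap_brain() -> Brain:
    return Brain([DeterministicGate([0], [1], [0, 1]),
                  DeterministicGate([1], [0], [0, 1])],
                 n_nodes=2, n_sensors=0, n_motors=0)


def _xor_brain() -> Brain:
    # input patterns 00,01,10,11 -> both outputs = x XOR y
    return Brain([DeterministicGate([0, 1], [0, 1], [0, 3, 3, 0])],
                 n_nodes=2, n_sensors=0, n_motors=0)


def _coin_brain() -> Brain:
    return Brain([DecomposableGate([0], [0], [[0.5], [0.5]])],
                 n_nodes=1, n_sensors=0, n_motors=0)


def _feedback_probe_brain(delta: float = 0.1, history_length: int = 1) -> Brain:
    """Nodes 0-1 are sensors (positive and negative reinforcement buttons);
    one decomposable feedback gate reads hidden node 2 and writes hidden
    nodes 2-3 from initially uniform factors."""
    fb = FeedbackParams(pos_node=0, neg_node=1, history_length=history_length,
                        pos_deltas=np.full(3, delta),
                        neg_deltas=np.full(3, delta))
    gate = DecomposableFeedbackGate([2], [2, 3],
                                    [[0.5, 0.5], [0.5, 0.5]], fb)
    return Brain([gate], n_nodes=4, n_sensors=2, n_motors=0)


def _corridor_world(length: int = 34, spawn_distance: int = 32) -> GridWorld:
    """A 1-cell-high corridor with the goal at the east end; every arrow
    points east (forward for an east-facing animat)."""
    width = length + 2
    top = "#" * width
    middle = "#" + "E" * (length - 1) + "G" + "#"
    text = "\n".join([top, middle, top])
    return world_from_text(text, spawn_distance=spawn_distance)


def _open_world_5x5() -> GridWorld:
    # arrow/distance fields are recomputed from the wall mask and goal
    text = "\n".join(["#####",
                      "#...#",
                      "#.G.#",
                      "#...#",
                      "#####"])
    return world_from_text(text, spawn_distance=2)


def make_fixture(name: str, **kwargs):
    """Build a named fixture brain or world."""
    builders = {
        "copy_brain": _copy_brain,
        "swap_brain": _swap_brain,
        "xor_brain": _xor_brain,
        "coin_brain": _coin_brain,
        "feedback_probe_brain": _feedback_probe_brain,
        "corridor_world": _corridor_world,
        "open_world_5x5": _open_world_5x5,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return builders[name](**kwargs)
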