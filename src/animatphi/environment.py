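"""The lattice navigation task with action-result indirection.

An animat lives on a 2-D grid whose border (and a few interior cells) are
walls.  One non-wall cell is the goal; every other reachable cell carries
an arrow pointing along a shortest path toward the goal (computed with
Dijkstra on the 4-neighbourhood).  The animat senses only how the arrow on
its current cell relates to its own heading, and emits one of four abstract
actions A-D.  Which action produces which result (turn left 90 deg, turn
right 90 deg, idle, move forward) is set by one of the 24 possible
action-to-result bijections, so the animat must discover the mapping of the
current episode by trial and error -- the learning problem.  Reaching the
goal scores a point and teleports the animat to a fresh cell at a fixed
shortest-path distance from the goal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .brain import Brain


class Result(IntEnum):
    """What an action does once the mapping is applied."""

    IDLE = 0
    FORWARD = 1
    LEFT = 2
    RIGHT = 3


#: orientations; N decreases the row index (origin top-left)
N, E, S, W = 0, 1, 2, 3
_ORIENT_DELTA = {N: (-1, 0), E: (0, 1), S: (1, 0), W: (0, -1)}
#: neighbour scan order for Dijkstra tie-breaking: N, E, S, W
_NEIGHBOUR_ORDER = (N, E, S, W)

#: fixed enumeration of all 24 action->result bijections; index a of a
#: mapping is the Result of action a (0=A .. 3=D)
ACTION_MAPPINGS: tuple[tuple[Result, ...], ...] = tuple(
    itertools.permutations((Result.IDLE, Result.FORWARD, Result.LEFT,
                            Result.RIGHT))
)


@dataclass
class GridWorld:
    """A lattice with wall mask, goal, and Dijkstra distance/arrow fields.

    ``distance[r, c]`` is the shortest-path distance to the goal (-1 where
    unreachable or wall); ``arrows[r, c]`` is the absolute orientation of
    the next cell on a shortest path (-1 at the goal, walls and unreachable
    cells).  ``spawn_cells`` are the (row, col) cells at exactly
    ``spawn_distance`` from the goal.
    """

    width: int
    height: int
    walls: np.ndarray
    goal: tuple[int, int]
    distance: np.ndarray
    arrows: np.ndarray
    spawn_distance: int
    spawn_cells: np.ndarray

    def is_wall(self, row: int, col: int) -> bool:
        return bool(self.walls[row, col])


class WorldBuildError(RuntimeError):
    pass


def _distance_field(walls: np.ndarray, goal: tuple[int, int]) -> np.ndarray:
    """Shortest-path distance to the goal over the 4-neighbourhood
    (unit edge weights), -1 where unreachable."""
    h, w = walls.shape
    idx = np.arange(h * w).reshape(h, w)
    rows_, cols_, data = [], [], []
    free = ~walls
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        src = free[max(0, dr):h + min(0, dr), max(0, dc):w + min(0, dc)]
        dst = free[max(0, -dr):h + min(0, -dr), max(0, -dc):w + min(0, -dc)]
        ok = src & dst
        a = idx[max(0, dr):h + min(0, dr), max(0, dc):w + min(0, dc)][ok]
        b = idx[max(0, -dr):h + min(0, -dr), max(0, -dc):w + min(0, -dc)][ok]
        rows_.append(a)
        cols_.append(b)
        data.append(np.ones(a.size))
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_), np.concatenate(cols_))),
        shape=(h * w, h * w),
    )
    dist = dijkstra(graph, indices=goal[0] * w + goal[1], unweighted=True)
    dist = dist.reshape(h, w)
    out = np.where(np.isfinite(dist), dist, -1).astype(np.int32)
    out[walls] = -1
    return out


def _arrow_field(walls: np.ndarray, distance: np.ndarray) -> np.ndarray:
    """Per-cell arrow: first neighbour (N, E, S, W order) one step closer
    to the goal."""
    h, w = walls.shape
    arrows = np.full((h, w), -1, dtype=np.int8)
    for r in range(h):
        for c in range(w):
            d = distance[r, c]
            if d <= 0:
                continue
            for ori in _NEIGHBOUR_ORDER:
                dr, dc = _ORIENT_DELTA[ori]
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and distance[rr, cc] == d - 1:
                    arrows[r, c] = ori
                    break
    return arrows


def build_world(width: int = 64, height: int = 64,
                obstacle_fraction: float = 0.05, spawn_distance: int = 32,
                rng: np.random.Generator | None = None,
                max_retries: int = 100) -> GridWorld:
    """Procedurally build a world: border walls, random interior obstacles,
    a uniformly chosen goal, and Dijkstra distance/arrow fields.

    Rebuilds with fresh draws (up to ``max_retries``) until at least one
    non-wall cell sits at exactly ``spawn_distance`` from the goal.
    """
    if width < 5 or height < 5:
        raise ValueError("world must be at least 5x5")
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(max_retries):
        walls = np.zeros((height, width), dtype=bool)
        walls[0, :] = walls[-1, :] = True
        walls[:, 0] = walls[:, -1] = True
        interior = rng.random((height - 2, width - 2)) < obstacle_fraction
        walls[1:-1, 1:-1] |= interior
        free = np.argwhere(~walls)
        if free.size == 0:
            continue
        goal = tuple(free[int(rng.integers(len(free)))])
        distance = _distance_field(walls, goal)
        spawn_cells = np.argwhere(distance == spawn_distance)
        if spawn_cells.size == 0:
            continue
        arrows = _arrow_field(walls, distance)
        return GridWorld(width=width, height=height, walls=walls,
                         goal=(int(goal[0]), int(goal[1])), distance=distance,
                         arrows=arrows, spawn_distance=spawn_distance,
                         spawn_cells=spawn_cells.astype(np.int64))
    raise WorldBuildError(
        f"no spawn cell at distance {spawn_distance} after {max_retries} builds"
    )


@dataclass
class AgentState:
    row: int
    col: int
    orientation: int  # N/E/S/W
    timestep: int = 0


def spawn_agent(world: GridWorld, rng: np.random.Generator,
                face_arrow: bool = False) -> AgentState:
    """Place the animat on a uniformly drawn cell at the spawn distance,
    facing a uniformly random direction (or the cell's arrow)."""
    r, c = world.spawn_cells[int(rng.integers(len(world.spawn_cells)))]
    ori = int(world.arrows[r, c]) if face_arrow else int(rng.integers(4))
    return AgentState(row=int(r), col=int(c), orientation=ori)


def sensor_encoding(world: GridWorld, agent: AgentState) -> np.ndarray:
    """One-hot 4-bit percept of the arrow under the animat.

    Bit 0 fires when the cell carries no arrow (stay put), bit 1 when the
    arrow requires a right turn (including the 180-degree case), bit 2 when
    the animat already faces the arrow (go forward), bit 3 when it requires
    a left turn.
    """
    sensors = np.zeros(4, dtype=np.uint8)
    arrow = int(world.arrows[agent.row, agent.col])
    if arrow < 0:
        sensors[0] = 1
        return sensors
    rel = (arrow - agent.orientation) % 4
    if rel == 0:
        sensors[2] = 1
    elif rel == 3:
        sensors[3] = 1
    else:  # rel 1 (right) or 2 (behind -> resolved as right turn)
        sensors[1] = 1
    return sensors


def step(world: GridWorld, agent: AgentState, action: int,
         mapping: tuple[Result, ...], rng: np.random.Generator,
         face_arrow_on_spawn: bool = False) -> bool:
    """Apply one action under ``mapping``; returns True on a goal arrival.

    Turns change orientation only; forward moves one cell unless blocked by
    a wall (then a no-op); idle changes nothing.  On reaching the goal the
    animat is respawned at a fresh spawn-distance cell.
    """
    result = mapping[action]
    if result == Result.LEFT:
        agent.orientation = (agent.orientation - 1) % 4
    elif result == Result.RIGHT:
        agent.orientation = (agent.orientation + 1) % 4
    elif result == Result.FORWARD:
        dr, dc = _ORIENT_DELTA[agent.orientation]
        rr, cc = agent.row + dr, agent.col + dc
        if not world.walls[rr, cc]:
            agent.row, agent.col = rr, cc
    agent.timestep += 1
    if (agent.row, agent.col) == world.goal:
        fresh = spawn_agent(world, rng, face_arrow=face_arrow_on_spawn)
        agent.row, agent.col, agent.orientation = (fresh.row, fresh.col,
                                                   fresh.orientation)
        return True
    return False


@dataclass
class EpisodeResult:
    """Outcome of one lifetime in one environment variant."""

    goals_reached: int
    action_counts: np.ndarray  # per Result value, sums to the lifetime
    state_trace: np.ndarray | None  # packed 16-bit states, one per timestep
    checkpoints: list = field(default_factory=list)  # (timestep, Brain snapshot)
    mapping_index: int | None = None
    detail: list | None = None  # per-step rows when requested

    @property
    def lifetime(self) -> int:
        return int(self.action_counts.sum())

    def detail_to_csv(self) -> str:
        """Per-timestep trace as CSV: timestep, the 16 node bits, action
        letter, position, orientation and goal event.  Requires the episode
        to have been run with ``record_detail=True``."""
        if self.detail is None:
            raise ValueError("episode was run without record_detail=True")
        n_bits = 16
        header = ("timestep," + ",".join(f"node{k}" for k in range(n_bits))
                  + ",action,col,row,orientation,goal_event")
        lines = [header]
        for t, state, action, row, col, ori, goal in self.detail:
            bits = ",".join(str((state >> k) & 1) for k in range(n_bits))
            lines.append(f"{t},{bits},{'ABCD'[action]},{col},{row},"
                         f"{'NESW'[ori]},{int(goal)}")
        return "\n".join(lines) + "\n"


class OraclePolicy:
    """Reference policy that knows the true action-result mapping and always
    requests the result the arrow asks for."""

    def __init__(self, mapping: tuple[Result, ...]):
        self.inverse = {result: action for action, result in enumerate(mapping)}

    def act(self, sensors: np.ndarray, rng: np.random.Generator) -> int:
        if sensors[2]:
            return self.inverse[Result.FORWARD]
        if sensors[1]:
            return self.inverse[Result.RIGHT]
        if sensors[3]:
            return self.inverse[Result.LEFT]
        return self.inverse[Result.IDLE]


def run_episode(controller, world: GridWorld, mapping,
                rng: np.random.Generator, lifetime: int = 512,
                checkpoint_stride: int | None = None,
                record_trace: bool = True,
                record_detail: bool = False,
                face_arrow_on_spawn: bool = False,
                mapping_index: int | None = None) -> EpisodeResult:
    """Run one lifetime of ``controller`` (a :class:`Brain` or a policy with
    an ``act(sensors, rng)`` method) in ``world`` under ``mapping``.

    The two motor bits decode to an action as ``m0 * 2 + m1`` (00=A .. 11=D).
    The state trace records the packed node state at each timestep, sensors
    included, *before* the update -- consecutive entries are the transitions
    the brain experienced.  When ``checkpoint_stride`` is set, a deep brain
    snapshot is taken at timesteps 0, stride, 2*stride, ... for per-time-point
    TPM analyses.
    """
    is_brain = isinstance(controller, Brain)
    agent = spawn_agent(world, rng, face_arrow=face_arrow_on_spawn)
    counts = np.zeros(4, dtype=np.int64)
    goals = 0
    trace = np.zeros(lifetime, dtype=np.uint32) if (record_trace and is_brain) \
        else None
    checkpoints = []
    detail = [] if record_detail else None
    for t in range(lifetime):
        if is_brain and checkpoint_stride and t % checkpoint_stride == 0:
            checkpoints.append((t, controller.snapshot()))
        sensors = sensor_encoding(world, agent)
        if is_brain:
            controller.node_states[: controller.n_sensors] = sensors
            if trace is not None:
                trace[t] = controller.packed_state()
            motors = controller.step(sensors, rng)
            action = int(motors[0]) * 2 + int(motors[1])
        else:
            action = int(controller.act(sensors, rng))
        counts[int(mapping[action])] += 1
        pre_row, pre_col, pre_ori = agent.row, agent.col, agent.orientation
        goal_event = step(world, agent, action, mapping, rng,
                          face_arrow_on_spawn=face_arrow_on_spawn)
        if goal_event:
            goals += 1
        if detail is not None:
            state = controller.packed_state() if is_brain else 0
            detail.append((t, state, action, pre_row, pre_col, pre_ori,
                           goal_event))
    return EpisodeResult(goals_reached=goals, action_counts=counts,
                         state_trace=trace, checkpoints=checkpoints,
                         mapping_index=mapping_index, detail=detail)


def evaluate_all_mappings(brain_factory, world: GridWorld,
                          rng: np.random.Generator, lifetime: int = 512,
                          mapping_indices=None, learning_enabled: bool = True,
                          record_trace: bool = False,
                          face_arrow_on_spawn: bool = False):
    """Total goals over the action-result mapping variants.

    ``brain_factory`` is either a :class:`Brain` (reset to its naive state
    before each variant so every mapping is learned from scratch) or a
    callable taking the mapping index and producing a fresh controller.
    Returns ``(g_total, per-mapping EpisodeResults)``.
    """
    if mapping_indices is None:
        mapping_indices = range(len(ACTION_MAPPINGS))
    results = []
    total = 0
    for m in mapping_indices:
        if isinstance(brain_factory, Brain):
            controller = brain_factory.reset("both")
            controller.learning_enabled = learning_enabled
        else:
            controller = brain_factory(m)
        res = run_episode(controller, world, ACTION_MAPPINGS[m], rng,
                          lifetime=lifetime, record_trace=record_trace,
                          face_arrow_on_spawn=face_arrow_on_spawn,
                          mapping_index=m)
        total += res.goals_reached
        results.append(res)
    return total, results


# -- plain-text world I/O -------------------------------------------------

_ARROW_CHARS = "NESW"


def world_to_text(world: GridWorld) -> str:
    """Plain-text grid: ``#`` walls, ``G`` goal, N/E/S/W arrows, ``.`` for
    arrowless reachable-free cells."""
    lines = []
    for r in range(world.height):
        chars = []
        for c in range(world.width):
            if world.walls[r, c]:
                chars.append("#")
            elif (r, c) == world.goal:
                chars.append("G")
            elif world.arrows[r, c] >= 0:
                chars.append(_ARROW_CHARS[world.arrows[r, c]])
            else:
                chars.append(".")
        lines.append("".join(chars))
    return "\n".join(lines) + "\n"


def world_from_text(text: str, spawn_distance: int) -> GridWorld:
    """Rebuild a world from :func:`world_to_text` output; distance and arrow
    fields are recomputed from the wall mask and goal."""
    rows = [line for line in text.strip("\n").split("\n")]
    height, width = len(rows), len(rows[0])
    walls = np.zeros((height, width), dtype=bool)
    goal = None
    for r, line in enumerate(rows):
        for c, ch in enumerate(line):
            if ch == "#":
                walls[r, c] = True
            elif ch == "G":
                goal = (r, c)
    if goal is None:
        raise ValueError("world text has no goal cell 'G'")
    distance = _distance_field(walls, goal)
    arrows = _arrow_field(walls, distance)
    spawn_cells = np.argwhere(distance == spawn_distance)
    if spawn_cells.size == 0:
        raise WorldBuildError(f"no cell at spawn distance {spawn_distance}")
    return GridWorld(width=width, height=height, walls=walls, goal=goal,
                     distance=distance, arrows=arrows,
                     spawn_distance=spawn_distance,
                     spawn_cells=spawn_cells.astype(np.int64))
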