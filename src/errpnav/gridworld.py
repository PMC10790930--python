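"""Discretized 3-D navigation environment with an A* optimal-action oracle.

The robot's end-effector moves a block through a 21 x 21 x 11 cell grid (the
continuous workspace clipped to discrete cells), taking one of six unit
moves — left, right, forward, backward, down, up — per step.  A wall of
blocked cells stands between the start region and the goal; the agent must
climb over it.  Observations are 8-dimensional: the three cell coordinates
normalized to [0, 1] plus five normalized laser readings (free cells along
fixed rays).  Moves into blocked cells or out of bounds are collisions: the
agent stays in place and the episode continues (a config flag makes
collisions terminal).  Reaching the goal gives sparse reward 1 and ends the
episode; episodes are capped at ``max_steps``.

The *optimal action* at any cell is the first move of a shortest
obstacle-avoiding path to the goal computed by A* with the Manhattan
heuristic (ties broken deterministically by action index) — the "green
arrow" shown to the observing human.

The wall geometry, laser rays and reward magnitudes are documented package
assumptions (see docs/methods.md) and are exposed as configuration.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

# action index -> unit move; order is part of the interface
ACTIONS = (
    (-1, 0, 0),  # 0 left   (-x)
    (1, 0, 0),   # 1 right  (+x)
    (0, 1, 0),   # 2 forward (+y)
    (0, -1, 0),  # 3 backward (-y)
    (0, 0, -1),  # 4 down   (-z)
    (0, 0, 1),   # 5 up     (+z)
)
ACTION_NAMES = ("left", "right", "forward", "backward", "down", "up")
N_ACTIONS = 6

# default laser ray directions: -x, +x, -y, +y, -z
LASER_RAYS = ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1))


@dataclass(frozen=True)
class GridState:
    """Observation: 3 normalized coordinates + 5 normalized laser readings."""

    position: tuple       # normalized (x, y, z) in [0, 1]
    lasers: tuple         # 5 floats in [0, 1]

    def vector(self) -> np.ndarray:
        v = np.array(self.position + self.lasers, dtype=np.float64)
        assert v.shape == (8,)
        return v


@dataclass(frozen=True)
class Transition:
    state: GridState
    action: int
    reward: float
    next_state: GridState
    done: bool
    collision: bool
    success: bool


def default_wall(dims: tuple, wall_top: int | None = None) -> set:
    """Full-width wall at the middle y-plane rising from the floor, leaving
    clearance above.  ``wall_top`` is the highest blocked z-index; the
    default is half the z extent (z-index 5 of 10 at full scale)."""
    wall_y = dims[1] // 2
    if wall_top is None:
        wall_top = (dims[2] - 1) // 2       # blocked z in [0, wall_top]
    if wall_top >= dims[2] - 1:
        raise ValueError("wall must leave clearance at the top")
    return {(x, wall_y, z)
            for x in range(dims[0]) for z in range(wall_top + 1)}


def default_start_region(dims: tuple) -> list:
    """6 x 11 floor-level rectangle on the near (-y) side of the wall,
    centered in x; clipped for small worlds."""
    depth = min(6, dims[1] // 2)
    width = min(11, dims[0])
    x0 = (dims[0] - width) // 2
    return [(x, y, 0)
            for y in range(depth) for x in range(x0, x0 + width)]


class GridWorld:
    """The discrete navigation task.

    Parameters
    ----------
    dims : tuple
        Grid dimensions (x, y, z); default (21, 21, 11).
    max_steps : int
        Episode step cap (default 160).
    laser_max_range : int
        Normalization range for laser readings, in cells.
    terminal_collision : bool
        End the episode on collision (default False: the agent stays put and
        the episode continues, so collision transitions populate replay).
    resample_goal : bool
        When False (default), the goal is sampled once — on the first
        reset — and kept for the world's lifetime; only the start position
        is re-randomized per episode.  The goal position stays fixed during
        a training run (the observation carries no goal information, so a
        per-episode goal would make the task unobservable); different seeds
        give different goals.  Set True to resample the goal every episode.
    """

    def __init__(self, dims: tuple = (21, 21, 11), max_steps: int = 160,
                 laser_max_range: int = 5, blocked: set | None = None,
                 start_region: list | None = None,
                 terminal_collision: bool = False,
                 goal_reward: float = 1.0, resample_goal: bool = False,
                 wall_top: int | None = None):
        self.dims = tuple(int(d) for d in dims)
        if any(d < 3 for d in self.dims):
            raise ValueError("grid dimensions must be at least 3 cells")
        self.max_steps = int(max_steps)
        self.laser_max_range = int(laser_max_range)
        self.blocked = (set(blocked) if blocked is not None
                        else default_wall(self.dims, wall_top))
        self.start_region = (list(start_region) if start_region is not None
                             else default_start_region(self.dims))
        self.start_region = [c for c in self.start_region
                             if c not in self.blocked]
        if not self.start_region:
            raise ValueError("start region is empty after blocking")
        self.terminal_collision = terminal_collision
        self.goal_reward = float(goal_reward)
        self.resample_goal = resample_goal
        self.wall_y = self.dims[1] // 2
        self.agent: tuple | None = None
        self.goal: tuple | None = None
        self.step_count = 0
        self._done = True

    # ---- geometry helpers ----
    def in_bounds(self, cell: tuple) -> bool:
        return all(0 <= c < d for c, d in zip(cell, self.dims))

    def is_free(self, cell: tuple) -> bool:
        return self.in_bounds(cell) and cell not in self.blocked

    def goal_candidates(self) -> list:
        """Floor-level cells on the far (+y) side of the wall."""
        return [(x, y, 0)
                for y in range(self.wall_y + 1, self.dims[1])
                for x in range(self.dims[0])
                if (x, y, 0) not in self.blocked]

    # ---- observation ----
    def lasers(self, position: tuple) -> tuple:
        """Normalized free-cell distance along each configured ray."""
        readings = []
        for ray in LASER_RAYS:
            free = 0
            cell = position
            while free < self.laser_max_range:
                cell = tuple(c + r for c, r in zip(cell, ray))
                if not self.is_free(cell):
                    break
                free += 1
            readings.append(free / self.laser_max_range)
        return tuple(readings)

    def state_at(self, position: tuple) -> GridState:
        norm = tuple(c / (d - 1) for c, d in zip(position, self.dims))
        return GridState(position=norm, lasers=self.lasers(position))

    def observe(self) -> GridState:
        return self.state_at(self.agent)

    # ---- episode control ----
    def reset(self, seed=None, rng: np.random.Generator | None = None) -> GridState:
        """Sample (start, goal) until an A* path exists; reset the counter."""
        if rng is None:
            rng = np.random.default_rng(seed)
        goals = self.goal_candidates()
        if not goals:
            raise RuntimeError("no feasible goal cells")
        keep_goal = self.goal is not None and not self.resample_goal
        for _ in range(100):
            agent = self.start_region[rng.integers(len(self.start_region))]
            goal = self.goal if keep_goal \
                else goals[rng.integers(len(goals))]
            if agent != goal and astar_path(self, agent, goal) is not None:
                self.agent, self.goal = agent, goal
                self.step_count = 0
                self._done = False
                return self.observe()
        raise RuntimeError("no feasible (start, goal) pair after 100 attempts")

    def step(self, action: int) -> Transition:
        if self._done:
            raise RuntimeError("episode is done; call reset()")
        if not (0 <= action < N_ACTIONS):
            raise ValueError(f"action index {action} outside 0-{N_ACTIONS - 1}")
        state = self.observe()
        target = tuple(c + d for c, d in zip(self.agent, ACTIONS[action]))
        collision = not self.is_free(target)
        if not collision:
            self.agent = target
        self.step_count += 1
        success = self.agent == self.goal
        done = success or self.step_count >= self.max_steps \
            or (collision and self.terminal_collision)
        reward = self.goal_reward if success else 0.0
        self._done = done
        return Transition(state=state, action=action, reward=reward,
                          next_state=self.observe(), done=done,
                          collision=collision, success=success)

    # conventional episodic-control metadata
    @property
    def observation_size(self) -> int:
        return 8

    @property
    def n_actions(self) -> int:
        return N_ACTIONS


def rich_reward(position_norm, goal_norm, sparse: float = 0.0,
                gain: float = 1.0) -> float:
    """Sparse term plus a negative distance-shaping term (optional baseline).

    ``position_norm`` and ``goal_norm`` are normalized coordinates in
    [0, 1]^3; the shaping term is -gain * Euclidean distance.
    """
    d = float(np.linalg.norm(np.asarray(position_norm, dtype=float)
                             - np.asarray(goal_norm, dtype=float)))
    return sparse - gain * d


# ------------------------------------------------------------------- A*

def _manhattan(a: tuple, b: tuple) -> int:
    return sum(abs(x - y) for x, y in zip(a, b))


def astar_path(world: GridWorld, start: tuple, goal: tuple,
               heuristic=_manhattan) -> list | None:
    """Shortest 6-connected path from start to goal, or None if unreachable.

    Deterministic: ties are broken by heuristic value, then by insertion
    order, and successors are expanded in fixed action-index order.
    """
    if start == goal:
        return [start]
    if not world.is_free(start) or not world.is_free(goal):
        return None
    counter = 0
    open_heap = [(heuristic(start, goal), heuristic(start, goal), counter, start)]
    g_score = {start: 0}
    came_from = {}
    closed = set()
    while open_heap:
        _, _, _, current = heapq.heappop(open_heap)
        if current in closed:
            continue
        if current == goal:
            path = [current]
            while current in came_from:
                current = came_from[current]
                path.append(current)
            return path[::-1]
        closed.add(current)
        g = g_score[current]
        for move in ACTIONS:
            nb = tuple(c + d for c, d in zip(current, move))
            if not world.is_free(nb) or nb in closed:
                continue
            tentative = g + 1
            if tentative < g_score.get(nb, np.inf):
                g_score[nb] = tentative
                came_from[nb] = current
                counter += 1
                h = heuristic(nb, goal)
                heapq.heappush(open_heap, (tentative + h, h, counter, nb))
    return None


def shortest_path_length(world: GridWorld, start: tuple, goal: tuple) -> int:
    """Number of moves on a shortest path (0 when start == goal)."""
    path = astar_path(world, start, goal)
    if path is None:
        raise ValueError("goal unreachable from start")
    return len(path) - 1


def optimal_action(world: GridWorld, position: tuple | None = None,
                   goal: tuple | None = None) -> int | None:
    """First move of a shortest path — the "green arrow".

    Returns the action index, or None when already at the goal (zero-length
    path).  Raises if the goal is unreachable.
    """
    position = world.agent if position is None else position
    goal = world.goal if goal is None else goal
    path = astar_path(world, position, goal)
    if path is None:
        raise ValueError("goal unreachable from position")
    if len(path) == 1:
        return None
    move = tuple(b - a for a, b in zip(path[0], path[1]))
    return ACTIONS.index(move)


# ------------------------------------------------------- trial scheduler

@dataclass(frozen=True)
class TrialRecord:
    """One scheduled robot action observed by the (simulated) human."""

    position: tuple
    state: GridState
    executed_action: int
    optimal_action: int
    is_error: bool


def schedule_trials(world: GridWorld, n: int, error_fraction: float,
                    seed: int = 0) -> list:
    """Schedule n observed robot movements with a fixed error count.

    Exactly ``round(n * error_fraction)`` trials execute a uniformly random
    non-optimal action; the rest execute the A* optimal action.  The robot
    actually performs each executed action (collisions leave it in place);
    episodes are re-seeded from the world's reset whenever one ends.  The
    resulting error/true flag sequence drives the synthetic-EEG event labels
    and the BCI calibration protocol.
    """
    from .simulate import error_schedule

    rng = np.random.default_rng(seed)
    flags = error_schedule(n, error_fraction, rng)
    world.reset(rng=rng)
    trials = []
    for is_error in flags:
        opt = optimal_action(world)
        if opt is None:  # degenerate: already at goal
            world.reset(rng=rng)
            opt = optimal_action(world)
        if is_error:
            others = [a for a in range(N_ACTIONS) if a != opt]
            executed = int(others[rng.integers(len(others))])
        else:
            executed = int(opt)
        trials.append(TrialRecord(position=world.agent,
                                  state=world.observe(),
                                  executed_action=executed,
                                  optimal_action=int(opt),
                                  is_error=bool(is_error)))
        tr = world.step(executed)
        if tr.done:
            world.reset(rng=rng)
    return trials
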