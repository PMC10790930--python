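"""Grid environment: geometry, collisions, A* oracle, lasers, scheduler."""

from collections import deque

import numpy as np
import pytest

from errpnav.gridworld import (ACTIONS, ACTION_NAMES, GridWorld, N_ACTIONS,
                               astar_path, optimal_action, rich_reward,
                               schedule_trials, shortest_path_length)


def bfs_distance(world, start, goal):
    """Independent breadth-first-search oracle for shortest path length."""
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        cell, d = frontier.popleft()
        for move in ACTIONS:
            nb = tuple(c + m for c, m in zip(cell, move))
            if nb == goal:
                return d + 1
            if world.is_free(nb) and nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return None


def open_world(dims=(5, 5, 3), **kw):
    return GridWorld(dims=dims, blocked=set(),
                     start_region=[(0, 0, 0)], **kw)


class TestGeometry:
    def test_full_scale_defaults(self):
        w = GridWorld()
        assert w.dims == (21, 21, 11)
        assert w.max_steps == 160
        # wall occupies the middle y-plane up to z-index 5 (clearance above)
        assert (0, 10, 5) in w.blocked and (0, 10, 6) not in w.blocked
        assert len(w.start_region) == 6 * 11

    def test_observation_vector_contract(self):
        w = GridWorld(dims=(9, 9, 5))
        rng = np.random.default_rng(0)
        for _ in range(20):
            obs = w.reset(rng=rng).vector()
            assert obs.shape == (8,)
            assert np.all(obs >= 0) and np.all(obs <= 1)

    def test_resets_start_in_start_region_and_feasible(self):
        w = GridWorld(dims=(9, 9, 5), resample_goal=True)
        rng = np.random.default_rng(1)
        region = set(w.start_region)
        for _ in range(200):
            w.reset(rng=rng)
            assert w.agent in region
            assert astar_path(w, w.agent, w.goal) is not None

    def test_fixed_seed_reproducible(self):
        starts = []
        for _ in range(2):
            w = GridWorld(dims=(9, 9, 5))
            rng = np.random.default_rng(7)
            starts.append([(w.reset(rng=rng).position, w.goal)
                           for _ in range(10)])
        assert starts[0] == starts[1]

    def test_goal_fixed_across_episodes_by_default(self):
        w = GridWorld(dims=(9, 9, 5))
        rng = np.random.default_rng(3)
        w.reset(rng=rng)
        goal = w.goal
        for _ in range(5):
            w.reset(rng=rng)
            assert w.goal == goal


class TestStep:
    def test_reaching_goal(self):
        w = open_world()
        w.agent, w.goal, w._done, w.step_count = (0, 0, 0), (1, 0, 0), False, 0
        tr = w.step(1)  # right
        assert tr.success and tr.done and tr.reward == 1.0

    def test_boundary_collision_leaves_agent_in_place(self):
        w = open_world()
        w.agent, w.goal, w._done, w.step_count = (0, 0, 0), (4, 4, 0), False, 0
        tr = w.step(0)  # left at x=0
        assert tr.collision and not tr.success
        assert w.agent == (0, 0, 0)
        assert tr.reward == 0.0

    def test_step_cap_ends_episode_without_success(self):
        w = open_world(max_steps=160)
        w.agent, w.goal, w._done, w.step_count = (0, 0, 0), (4, 4, 2), False, 0
        for i in range(160):  # bounce against the wall
            tr = w.step(0)
        assert tr.done and not tr.success
        with pytest.raises(RuntimeError):
            w.step(0)

    def test_invalid_action_rejected(self):
        w = open_world()
        w.reset(seed=0)
        with pytest.raises(ValueError):
            w.step(6)

    def test_collision_never_moves_and_success_excludes_collision(self):
        w = GridWorld(dims=(9, 9, 5))
        rng = np.random.default_rng(5)
        w.reset(rng=rng)
        for _ in range(500):
            before = w.agent
            tr = w.step(int(rng.integers(N_ACTIONS)))
            if tr.collision:
                assert w.agent == before
                assert not tr.success
            if tr.done:
                w.reset(rng=rng)


class TestLasers:
    def test_against_wall_reads_zero(self):
        w = GridWorld(dims=(9, 9, 5))
        # cell directly in front of the wall (wall at y=4): +y ray blocked
        readings = w.lasers((4, 3, 0))
        assert readings[3] == 0.0          # +y
        assert readings[4] == 0.0          # -z at floor level

    def test_open_space_clips_to_one(self):
        w = open_world(dims=(15, 15, 15), laser_max_range=5)
        readings = w.lasers((7, 7, 7))
        assert readings == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_built_corridor(self):
        # 7x1x1 corridor with a block at x=5: from x=2 free cells are
        # -x: 2 (clip range 5 -> 0.4), +x: 2 (blocked at 5 -> 0.4)
        blocked = {(5, 0, 0)}
        w = GridWorld(dims=(7, 3, 3), blocked=blocked,
                      start_region=[(0, 0, 0)], laser_max_range=5)
        r = w.lasers((2, 0, 0))
        assert r[0] == pytest.approx(2 / 5)   # -x to boundary
        assert r[1] == pytest.approx(2 / 5)   # +x to the block
        assert r[2] == pytest.approx(0.0)     # -y at boundary
        assert r[4] == pytest.approx(0.0)     # -z at floor


class TestAStar:
    def test_one_step_to_goal(self):
        w = open_world()
        assert optimal_action(w, (1, 1, 0), (2, 1, 0)) == ACTION_NAMES.index("right")

    def test_start_equals_goal_is_distinct_noop(self):
        w = open_world()
        assert optimal_action(w, (1, 1, 0), (1, 1, 0)) is None

    def test_unreachable_goal_raises(self):
        blocked = {(1, y, z) for y in range(3) for z in range(3)}
        w = GridWorld(dims=(3, 3, 3), blocked=blocked,
                      start_region=[(0, 0, 0)])
        with pytest.raises(ValueError, match="unreachable"):
            optimal_action(w, (0, 0, 0), (2, 0, 0))

    def test_matches_bfs_on_random_worlds(self):
        """A* path length equals the BFS oracle on 200 random instances."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 200:
            dims = tuple(int(d) for d in rng.integers(3, 7, size=3))
            n_cells = dims[0] * dims[1] * dims[2]
            blocked = {tuple(int(c) for c in
                             (rng.integers(dims[0]), rng.integers(dims[1]),
                              rng.integers(dims[2])))
                       for _ in range(n_cells // 4)}
            free = [(x, y, z) for x in range(dims[0]) for y in range(dims[1])
                    for z in range(dims[2]) if (x, y, z) not in blocked]
            if len(free) < 2:
                continue
            start, goal = [free[i] for i in
                           rng.choice(len(free), size=2, replace=False)]
            w = GridWorld(dims=dims, blocked=blocked, start_region=[start])
            d_bfs = bfs_distance(w, start, goal)
            path = astar_path(w, start, goal)
            if d_bfs is None:
                assert path is None
            else:
                assert len(path) - 1 == d_bfs
            checked += 1

    def test_heuristic_invariance(self):
        """Path length identical under the zero heuristic (Dijkstra)."""
        rng = np.random.default_rng(12)
        w = GridWorld(dims=(9, 9, 5))
        for _ in range(20):
            w.reset(rng=rng)
            a = astar_path(w, w.agent, w.goal)
            b = astar_path(w, w.agent, w.goal, heuristic=lambda x, y: 0)
            assert len(a) == len(b)


class TestRichReward:
    def test_zero_at_goal_and_monotone(self):
        assert rich_reward((0.5, 0.5, 0.5), (0.5, 0.5, 0.5)) == 0.0
        near = rich_reward((0.4, 0.5, 0.5), (0.5, 0.5, 0.5))
        far = rich_reward((0.0, 0.5, 0.5), (0.5, 0.5, 0.5))
        assert far < near < 0

    def test_unit_cube_diagonal(self):
        assert rich_reward((0, 0, 0), (1, 1, 1), gain=2.0) == pytest.approx(
            -2.0 * np.sqrt(3))


class TestScheduleTrials:
    @pytest.mark.parametrize("n,frac,n_err", [(500, 0.20, 100),
                                              (400, 0.50, 200)])
    def test_exact_error_counts(self, n, frac, n_err):
        w = GridWorld(dims=(9, 9, 5))
        trials = schedule_trials(w, n, frac, seed=5)
        assert len(trials) == n
        assert sum(t.is_error for t in trials) == n_err

    def test_zero_fraction_executes_only_optimal(self):
        w = GridWorld(dims=(9, 9, 5))
        trials = schedule_trials(w, 60, 0.0, seed=1)
        assert all(t.executed_action == t.optimal_action for t in trials)

    def test_error_trials_execute_non_optimal(self):
        w = GridWorld(dims=(9, 9, 5))
        trials = schedule_trials(w, 60, 0.5, seed=2)
        for t in trials:
            if t.is_error:
                assert t.executed_action != t.optimal_action
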