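"""Deterministic gridworld MDP: maze geometry, actions, transitions, rewards.

The environment is a rectangular grid of cells, each either wall or open.
Open cells are the MDP states. From a non-goal state the agent may move in
the four cardinal directions; a move is *unavailable* (not a no-op) when it
would enter a wall or leave the grid. Goal cells carry a reward magnitude
and expose a single ``collect`` action that emits the reward and leads to an
absorbing terminal pseudo-state (represented by the index ``TERMINAL``).

A cell converted to a wall mid-run (a barrier) keeps its state index with an
empty action set, so agents' occupancy matrices keep fixed dimensions across
the manipulation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from math import inf
from typing import NamedTuple

import numpy as np

# Action slots. Collect is only ever available in goal (rewarded) cells.
N, E, S, W, COLLECT = 0, 1, 2, 3, 4
N_ACTIONS = 5
ACTION_NAMES = ("N", "E", "S", "W", "collect")
_DELTAS = {N: (0, -1), E: (1, 0), S: (0, 1), W: (-1, 0)}

#: Index of the absorbing terminal pseudo-state (its occupancy row is zero).
TERMINAL = -1

_MARKER_TO_LABEL = {
    "S": "S", "1": "S1", "2": "S2",
    "R": "R", "r": "R1", "Q": "R2",
    "B": "B",
}
#: Markers that denote reward (goal) locations in the map dialect.
REWARD_LABELS = ("R", "R1", "R2")


class GridParseError(ValueError):
    """Raised for malformed ASCII maps (ragged rows, unknown chars, ...)."""


class Transition(NamedTuple):
    """One experienced environment transition.

    ``r > 0`` only on collect, and collect always leads to ``TERMINAL``.
    Step stamps are assigned by the experience buffer, not the world.
    """

    s: int
    a: int
    r: float
    s_next: int  # state index or TERMINAL


@dataclass(frozen=True)
class GridWorld:
    """Immutable maze MDP over open cells of a parsed ASCII map.

    ``state_index`` is a bijection between open cells (at parse time) and
    ``0..n_states-1``; cells later blocked by :meth:`insert_wall` keep their
    index but have no available actions.
    """

    width: int
    height: int
    wall: tuple[tuple[bool, ...], ...]          # original walls, [row][col]
    labels: dict[str, tuple[int, int]]
    coord_of_state: tuple[tuple[int, int], ...]  # state -> (col, row)
    state_of_coord: dict[tuple[int, int], int]
    reward: tuple[float, ...]                    # per-state magnitude (>=0)
    is_goal: tuple[bool, ...]                    # collect-only states
    blocked: tuple[bool, ...]                    # inserted walls
    # caches (derived, rebuilt on every functional update)
    _avail: tuple[tuple[int, ...], ...] = field(repr=False, default=())
    _succ: np.ndarray | None = field(repr=False, default=None, compare=False)

    # -- construction -----------------------------------------------------

    @staticmethod
    def _derive(width, height, wall, state_of_coord, coord_of_state,
                is_goal, blocked):
        """Available-action lists and successor table for all states."""
        n = len(coord_of_state)
        succ = np.full((n, N_ACTIONS), TERMINAL, dtype=np.int64)
        avail = []
        for s, (c, r) in enumerate(coord_of_state):
            if blocked[s]:
                avail.append(())
                continue
            if is_goal[s]:
                avail.append((COLLECT,))
                continue
            acts = []
            for a in (N, E, S, W):
                dc, dr = _DELTAS[a]
                nc, nr = c + dc, r + dr
                if not (0 <= nc < width and 0 <= nr < height):
                    continue
                if wall[nr][nc]:
                    continue
                t = state_of_coord[(nc, nr)]
                if blocked[t]:
                    continue
                acts.append(a)
                succ[s, a] = t
            avail.append(tuple(acts))
        return tuple(avail), succ

    def _rebuild(self, **changes) -> "GridWorld":
        w = replace(self, **changes)
        avail, succ = GridWorld._derive(
            w.width, w.height, w.wall, w.state_of_coord, w.coord_of_state,
            w.is_goal, w.blocked)
        object.__setattr__(w, "_avail", avail)
        object.__setattr__(w, "_succ", succ)
        return w

    # -- basic queries ----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.coord_of_state)

    @property
    def successors(self) -> np.ndarray:
        """(n_states, 5) table of successor state indices (TERMINAL if n/a)."""
        return self._succ

    def state(self, cell_or_label) -> int:
        """State index of a (col, row) cell or a map label like ``"R1"``."""
        if isinstance(cell_or_label, str):
            cell_or_label = self.labels[cell_or_label]
        return self.state_of_coord[tuple(cell_or_label)]

    def open_states(self) -> list[int]:
        """Indices of currently open (non-blocked) cells."""
        return [s for s in range(self.n_states) if not self.blocked[s]]

    def available_actions(self, s: int) -> tuple[int, ...]:
        """Ordered available actions at ``s``: (N, E, S, W) or (collect,)."""
        if s == TERMINAL:
            raise ValueError("TERMINAL has no actions")
        return self._avail[s]

    # -- dynamics ---------------------------------------------------------

    def step(self, s: int, a: int) -> Transition:
        """Take action ``a`` in state ``s`` (deterministic).

        Raises if ``a`` is not available in ``s``; agents select among
        available actions only.
        """
        if a not in self._avail[s]:
            raise ValueError(
                f"action {ACTION_NAMES[a]} unavailable in state {s} "
                f"{self.coord_of_state[s]}")
        if a == COLLECT:
            return Transition(s, a, self.reward[s], TERMINAL)
        return Transition(s, a, 0.0, int(self._succ[s, a]))

    # -- functional updates ----------------------------------------------

    def add_goal(self, cell_or_label, magnitude: float = 0.0) -> "GridWorld":
        """Mark an open cell as an absorbing goal with the given reward.

        Goal cells expose only ``collect``; a zero magnitude is allowed (a
        known reward location whose reward has not yet been introduced).
        """
        s = self.state(cell_or_label)
        if self.blocked[s]:
            raise ValueError("cannot place a goal on a blocked cell")
        if magnitude < 0:
            raise ValueError("reward magnitude must be >= 0")
        reward = list(self.reward)
        goal = list(self.is_goal)
        reward[s] = float(magnitude)
        goal[s] = True
        return self._rebuild(reward=tuple(reward), is_goal=tuple(goal))

    def set_reward(self, cell_or_label, magnitude: float) -> "GridWorld":
        """Set the reward magnitude at a cell, collapsing it to a goal.

        Setting 0 at a non-goal cell is a no-op (no zero-reward collect
        state is introduced); raising the magnitude of an existing goal
        keeps geometry and indexing unchanged.
        """
        s = self.state(cell_or_label)
        if not self.is_goal[s] and magnitude == 0:
            return self
        return self.add_goal(cell_or_label, magnitude)

    def insert_wall(self, cell_or_label) -> "GridWorld":
        """Turn an open, unrewarded cell into a wall (barrier).

        The cell keeps its state index with an empty action set; all other
        states keep their indices and geometry.
        """
        s = self.state(cell_or_label)
        if self.blocked[s]:
            raise ValueError("cell is already a wall")
        if self.is_goal[s]:
            raise ValueError("cannot wall a rewarded cell")
        blocked = list(self.blocked)
        blocked[s] = True
        return self._rebuild(blocked=tuple(blocked))

    # -- oracle -----------------------------------------------------------

    def shortest_path_distances(self, goal_cell_or_label) -> np.ndarray:
        """BFS step counts from every state to the goal (inf if unreachable).

        Distances are over cardinal moves in the *current* world (blocked
        cells are impassable and unreachable).
        """
        g = self.state(goal_cell_or_label)
        if self.blocked[g]:
            raise ValueError("goal cell is a wall")
        dist = np.full(self.n_states, inf)
        dist[g] = 0.0
        q = deque([g])
        # predecessors: states with a cardinal move into the frontier cell
        preds: dict[int, list[int]] = {s: [] for s in range(self.n_states)}
        for s in range(self.n_states):
            for a in self._avail[s]:
                if a != COLLECT:
                    preds[int(self._succ[s, a])].append(s)
        while q:
            cur = q.popleft()
            for p in preds[cur]:
                if dist[p] == inf:
                    dist[p] = dist[cur] + 1
                    q.append(p)
        return dist


def parse_grid_map(text: str) -> GridWorld:
    """Parse the ASCII map dialect into a :class:`GridWorld`.

    ``#`` wall, ``.`` open, ``S``/``1``/``2`` start markers (S, S1, S2),
    ``R``/``r``/``Q`` reward markers (R, R1, R2), ``B`` future-barrier
    marker. Marker cells are open. No rewards are set by the parser; task
    protocols declare reward markers as goal cells.
    """
    rows = text.strip("\n").split("\n")
    if not rows or not rows[0]:
        raise GridParseError("empty map")
    width = len(rows[0])
    labels: dict[str, tuple[int, int]] = {}
    wall_rows: list[tuple[bool, ...]] = []
    for r, row in enumerate(rows):
        if len(row) != width:
            raise GridParseError(f"ragged row at line {r + 1}: "
                                 f"expected {width} cells, got {len(row)}")
        if row != row.rstrip():
            raise GridParseError(f"trailing whitespace at line {r + 1}")
        flags = []
        for c, ch in enumerate(row):
            if ch == "#":
                flags.append(True)
                continue
            flags.append(False)
            if ch == ".":
                continue
            if ch not in _MARKER_TO_LABEL:
                raise GridParseError(
                    f"unknown character {ch!r} at line {r + 1}, col {c + 1}")
            label = _MARKER_TO_LABEL[ch]
            if label in labels:
                raise GridParseError(
                    f"duplicate label {label} at line {r + 1}, col {c + 1}")
            labels[label] = (c, r)
        wall_rows.append(tuple(flags))
    wall = tuple(wall_rows)
    height = len(wall)
    coords = [(c, r) for r in range(height) for c in range(width)
              if not wall[r][c]]
    state_of_coord = {cell: i for i, cell in enumerate(coords)}
    n = len(coords)
    world = GridWorld(
        width=width, height=height, wall=wall, labels=labels,
        coord_of_state=tuple(coords), state_of_coord=state_of_coord,
        reward=(0.0,) * n, is_goal=(False,) * n, blocked=(False,) * n)
    return world._rebuild()


def available_actions(world: GridWorld, s: int) -> tuple[int, ...]:
    return world.available_actions(s)


def step(world: GridWorld, s: int, a: int, rng=None) -> Transition:
    # rng accepted for interface uniformity; transitions are deterministic
    return world.step(s, a)


def set_reward(world: GridWorld, cell, magnitude: float) -> GridWorld:
    return world.set_reward(cell, magnitude)


def insert_wall(world: GridWorld, cell) -> GridWorld:
    return world.insert_wall(cell)


def shortest_path_distances(world: GridWorld, goal) -> np.ndarray:
    return world.shortest_path_distances(goal)
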