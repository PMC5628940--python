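"""Reduction of task results to categorical flexibility verdicts.

The behavioural readout follows the simulation conventions: per-state
*median* value over runs, an implied policy pointing each open cell at its
highest-valued accessible neighbor, and a pass/fail verdict per (agent,
task) — pass iff greedily following the implied policy from the task's start
reaches the maximal-reward cell in exactly the shortest-path number of
steps, with no value ties along the way. A value-iteration oracle provides
the fully model-based reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .agents import AgentParams, make_agent
from .gridworld import COLLECT, GridWorld
from .protocols import TASK_NAMES, TaskResult, run_task

#: Two median values closer than this are a tie (float-median noise floor).
TIE_TOL = 1e-9


@dataclass(frozen=True)
class PolicyEntry:
    action: int            # cardinal slot or COLLECT
    target: int | None     # successor state (None for collect)
    tie: bool


# -- value maps and implied policies ----------------------------------------

def median_value_map(result: TaskResult) -> np.ndarray:
    """Per-state median value over runs (lower median for even run counts,
    fixed for bit-reproducibility)."""
    if not result.value_tables:
        raise ValueError("empty task result")
    stacked = np.sort(np.stack(result.value_tables), axis=0)
    return stacked[(stacked.shape[0] - 1) // 2]


def implied_policy(vmap: np.ndarray, world: GridWorld) -> dict[int, PolicyEntry]:
    """Arrow per open cell toward the accessible neighbor of maximal median
    value; rewarded cells collect; near-equal maxima are tie-flagged."""
    policy: dict[int, PolicyEntry] = {}
    succ = world.successors
    for s in world.open_states():
        acts = world.available_actions(s)
        if acts == (COLLECT,):
            policy[s] = PolicyEntry(COLLECT, None, False)
            continue
        targets = [int(succ[s, a]) for a in acts]
        vals = [float(vmap[t]) for t in targets]
        m = max(vals)
        best = [i for i, v in enumerate(vals) if v >= m - TIE_TOL]
        i = best[0]
        policy[s] = PolicyEntry(acts[i], targets[i], len(best) > 1)
    return policy


def policy_optimal(pmap: dict[int, PolicyEntry], world: GridWorld,
                   start) -> bool:
    """Pass iff the implied policy reaches the maximal-reward cell from
    ``start`` in exactly the shortest-path number of steps, tie-free."""
    start = world.state(start) if not isinstance(start, (int, np.integer)) \
        else int(start)
    rewards = np.asarray(world.reward)
    goal = int(np.argmax(rewards))
    if rewards[goal] <= 0:
        raise ValueError("world has no positive reward")
    d = world.shortest_path_distances(world.coord_of_state[goal])
    if not np.isfinite(d[start]):
        return False
    cur, steps = start, 0
    seen = set()
    while cur != goal:
        if cur in seen or steps > d[start]:
            return False
        seen.add(cur)
        entry = pmap.get(cur)
        if entry is None or entry.tie or entry.target is None:
            return False
        cur = entry.target
        steps += 1
    return steps == d[start]


# -- oracles ----------------------------------------------------------------

def value_iteration(world: GridWorld, gamma: float = 0.95,
                    tol: float = 1e-10) -> np.ndarray:
    """Optimal state values by Bellman-optimality iteration over available
    actions (collect pays the cell's reward and terminates)."""
    n = world.n_states
    succ = world.successors
    V = np.zeros(n)
    states = world.open_states()
    while True:
        delta = 0.0
        for s in states:
            acts = world.available_actions(s)
            if acts == (COLLECT,):
                v = world.reward[s]
            else:
                v = max(gamma * V[succ[s, a]] for a in acts)
            delta = max(delta, abs(v - V[s]))
            V[s] = v
        if delta < tol:
            return V


def greedy_actions(world: GridWorld, V: np.ndarray, gamma: float = 0.95,
                   tol: float = 1e-9) -> dict[int, tuple[int, ...]]:
    """Set of optimal actions per open state under a value function (more
    than one entry = tied state)."""
    out = {}
    succ = world.successors
    for s in world.open_states():
        acts = world.available_actions(s)
        if acts == (COLLECT,):
            out[s] = (COLLECT,)
            continue
        q = [gamma * float(V[succ[s, a]]) for a in acts]
        m = max(q)
        out[s] = tuple(a for a, v in zip(acts, q) if v >= m - tol)
    return out


# -- the agent x task flexibility matrix ------------------------------------

#: The seven standard agent configurations (replay-sufficient and
#: replay-insufficient Dyna variants use k = 10000 and k = 10).
DEFAULT_CONFIGS: tuple[tuple[str, str, AgentParams], ...] = (
    ("onestep_td", "onestep_td", AgentParams()),
    ("sr_td", "sr_td", AgentParams()),
    ("sr_mb", "sr_mb", AgentParams()),
    ("sr_dyna_k10000", "sr_dyna",
     AgentParams(n_replay_per_step=10, k_post_change=10000)),
    ("sr_dyna_k10", "sr_dyna",
     AgentParams(n_replay_per_step=10, k_post_change=10)),
    ("dyna_q_k10000", "dyna_q",
     AgentParams(n_replay_per_step=10, k_post_change=10000)),
    ("dyna_q_k10", "dyna_q",
     AgentParams(n_replay_per_step=10, k_post_change=10)),
)


@dataclass
class FlexibilityResult:
    """Verdict table plus the underlying per-combination task results."""

    verdicts: pd.DataFrame                       # configs x tasks, pass/fail
    results: dict[tuple[str, str], TaskResult] = field(default_factory=dict)


def task_verdict(result: TaskResult) -> str:
    """Reduce one task result: median map -> implied policy -> verdict."""
    vmap = median_value_map(result)
    pmap = implied_policy(vmap, result.world)
    ok = policy_optimal(pmap, result.world, result.start_label)
    return "pass" if ok else "fail"


def _combo_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
               % (2 ** 31))


def flexibility_matrix(configs=DEFAULT_CONFIGS, tasks=TASK_NAMES,
                       n_runs: int = 500, seed: int = 0,
                       size: str = "full") -> FlexibilityResult:
    """Run every (agent configuration, task) combination and reduce each to
    its categorical pass/fail verdict."""
    table = {}
    results = {}
    for i, ((label, agent_name, params), task) in enumerate(
            itertools.product(configs, tasks)):
        res = run_task(
            task, lambda w: make_agent(agent_name, w, params),
            n_runs, _combo_seed(seed, i), size=size)
        results[(label, task)] = res
        table.setdefault(label, {})[task] = task_verdict(res)
    df = pd.DataFrame(table).T.reindex(
        index=[c[0] for c in configs], columns=list(tasks))
    return FlexibilityResult(df, results)


def parameter_sweep(grid: dict[str, list], configs=DEFAULT_CONFIGS,
                    tasks=TASK_NAMES, n_runs: int = 500, seed: int = 0,
                    size: str = "full") -> pd.DataFrame:
    """Verdicts over a lattice of parameter overrides.

    ``grid`` maps AgentParams field names to value lists; every lattice
    point overrides those fields in every configuration. The returned frame
    has one row per (setting, config, task) with the verdict and whether it
    differs from the default-parameter verdict.
    """
    base = flexibility_matrix(configs, tasks, n_runs, seed, size)
    names = list(grid)
    rows = []
    for j, values in enumerate(itertools.product(*(grid[n] for n in names))):
        overrides = dict(zip(names, values))
        if all(getattr(AgentParams(), k) == v for k, v in overrides.items()):
            fr = base  # degenerate point: identical to the default matrix
        else:
            cfgs = [(label, name, dc_replace(params, **overrides))
                    for label, name, params in configs]
            fr = flexibility_matrix(cfgs, tasks, n_runs,
                                    _combo_seed(seed, 10_000 + j), size)
        for label, _, _ in configs:
            for task in tasks:
                v = fr.verdicts.loc[label, task]
                rows.append({**overrides, "config": label, "task": task,
                             "verdict": v,
                             "differs_from_default":
                                 v != base.verdicts.loc[label, task]})
    return pd.DataFrame(rows)
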