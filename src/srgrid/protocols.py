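"""The revaluation task procedures.

Each task stages experience so that a *local* change (a new reward, a
barrier) is learned in isolation, and then asks whether the agent's value
function immediately implies the globally correct policy:

latent learning
    Reward-free exploration, then the reward at R1 is raised to 10 and
    experienced only by 20 single-step collect probes from R1 itself.
detour
    Exploration, reward at R raised to 10, 5 training trials from S, then a
    barrier is inserted at B and experienced only by 40 single-step probes
    from the cell immediately west of the barrier.
policy revaluation
    The full latent-learning procedure, 20 trials alternating starts S1/S2
    that end at R1, then a larger reward (20) appears at R2 and is
    experienced only by 20 single-step probes from R2.

Reward-marked cells are absorbing goal cells with reward 0 from the start of
every task (the manipulations *raise* their magnitude); reaching any goal
teleports the agent back to the phase's start state. Every protocol is a
pure function of (fixture, agent configuration, seed).

The full-scale variants use the 10x10 mazes with the standard step counts
(25000 / 10000 exploration steps, 500 runs); the ``small`` variants keep the
same topology and visit density at reduced scale for fast simulation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .agents import BaseAgent
from .gridworld import TERMINAL, GridWorld
from .maps import load_map

#: Per-trial step cap guarding against non-terminating episodes.
TRIAL_CAP = 10 ** 6

# (task, size) -> fixture name and exploration length. Small-scale
# exploration keeps roughly the full-scale visits-per-state density.
TASK_DEFS = {
    ("latent", "full"): {"map": "latent", "explore": 25000},
    ("latent", "small"): {"map": "latent_small", "explore": 6000},
    ("detour", "full"): {"map": "detour", "explore": 10000},
    ("detour", "small"): {"map": "detour_small", "explore": 2500},
    ("policy_reval", "full"): {"map": "policy_reval", "explore": 25000},
    ("policy_reval", "small"): {"map": "policy_reval_small", "explore": 6000},
}
TASK_NAMES = ("latent", "detour", "policy_reval")


@dataclass
class TaskResult:
    """Recorded outcome of n independent runs of one task protocol."""

    task: str
    start_label: str
    world: GridWorld                     # world at the final record point
    value_tables: list[np.ndarray] = field(default_factory=list)
    trial_lengths: list[list[int]] = field(default_factory=list)
    capped_trials: int = 0               # trials stopped by the step cap
    run_seeds: list[int] = field(default_factory=list)


class ProtocolError(ValueError):
    """Fixture/configuration does not satisfy a task's preconditions."""


def _goal_world(world: GridWorld) -> GridWorld:
    """Declare every reward marker of the map an absorbing zero-reward goal."""
    for label in ("R", "R1", "R2"):
        if label in world.labels:
            world = world.add_goal(label, 0.0)
    return world


def _label(world: GridWorld, *names: str) -> str:
    for name in names:
        if name in world.labels:
            return name
    raise ProtocolError(f"fixture is missing a marker among {names}")


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    master = random.Random(seed)
    return [master.randrange(2 ** 31) for _ in range(n_runs)]


def _explore(agent: BaseAgent, world: GridWorld, start: int, steps: int,
             rng) -> None:
    """Free exploration: teleport back to the start whenever a goal absorbs."""
    agent.place(world, start, rng)
    for _ in range(steps):
        tr = agent.step(world, rng)
        if tr.s_next == TERMINAL:
            agent.place(world, start, rng)


def _trial(agent: BaseAgent, world: GridWorld, start: int, rng,
           cap: int = TRIAL_CAP) -> tuple[int, bool]:
    """One episode from start to any terminal; returns (steps, capped).

    The inter-trial pause afterwards is an offline-replay opportunity for
    Dyna agents that experienced a change during the episode.
    """
    agent.place(world, start, rng)
    n = 0
    while True:
        tr = agent.step(world, rng)
        n += 1
        if tr.s_next == TERMINAL or n >= cap:
            agent.offline_replay(world, rng)
            return n, n >= cap and tr.s_next != TERMINAL


def _probes(agent: BaseAgent, world: GridWorld, s: int, count: int,
            rng) -> None:
    """Single-step probes: place at s, take exactly one step, repeat.

    The rest period following the probe phase is an offline-replay
    opportunity (the probes are where task changes are experienced).
    """
    for _ in range(count):
        agent.place(world, s, rng)
        agent.step(world, rng)
    agent.offline_replay(world, rng)


def run_latent_learning(agent_factory, n_runs: int, seed: int,
                        size: str = "full") -> TaskResult:
    """Latent-learning task: explore, raise the reward at R1, probe, record."""
    cfg = TASK_DEFS[("latent", size)]
    base = _goal_world(load_map(cfg["map"]))
    start_label = _label(base, "S", "S1")
    reward_label = _label(base, "R1", "R")
    start = base.state(start_label)
    result = TaskResult("latent", start_label, base)
    for run_seed in _run_seeds(seed, n_runs):
        rng = random.Random(run_seed)
        agent = agent_factory(base)
        _explore(agent, base, start, cfg["explore"], rng)
        world = base.set_reward(reward_label, 10.0)
        _probes(agent, world, world.state(reward_label), 20, rng)
        result.value_tables.append(agent.value_table(world))
        result.run_seeds.append(run_seed)
        result.world = world
    return result


def validate_detour_fixture(world: GridWorld) -> tuple[int, int]:
    """Check the detour preconditions; return the probe cell west of B.

    The barrier B must lie on a shortest trained S -> R path (otherwise the
    manipulation would not sever the learned route) and the cell immediately
    left of it must be open.
    """
    for lab in ("S", "R", "B"):
        _label(world, lab)
    start = world.state("S")
    d_to_r = world.shortest_path_distances("R")
    d_to_b = world.shortest_path_distances("B")
    if d_to_b[start] + d_to_r[world.state("B")] != d_to_r[start]:
        raise ProtocolError("barrier B is not on a shortest S->R path")
    bc, br = world.labels["B"]
    probe_cell = (bc - 1, br)
    if probe_cell not in world.state_of_coord:
        raise ProtocolError("no open cell immediately left of the barrier")
    return probe_cell


def run_detour(agent_factory, n_runs: int, seed: int,
               size: str = "full") -> TaskResult:
    """Detour task: explore, train to R, insert the barrier, probe, record."""
    cfg = TASK_DEFS[("detour", size)]
    base = _goal_world(load_map(cfg["map"]))
    start = base.state("S")
    probe_cell = validate_detour_fixture(base)
    result = TaskResult("detour", "S", base)
    for run_seed in _run_seeds(seed, n_runs):
        rng = random.Random(run_seed)
        agent = agent_factory(base)
        _explore(agent, base, start, cfg["explore"], rng)
        world = base.set_reward("R", 10.0)
        for _ in range(5):
            _, capped = _trial(agent, world, start, rng)
            result.capped_trials += capped
        world = world.insert_wall("B")
        _probes(agent, world, world.state(probe_cell), 40, rng)
        result.value_tables.append(agent.value_table(world))
        result.run_seeds.append(run_seed)
        result.world = world
    return result


def run_policy_revaluation(agent_factory, n_runs: int, seed: int,
                           size: str = "full") -> TaskResult:
    """Policy-revaluation task: latent learning, trials to R1, then R2 = 20."""
    cfg = TASK_DEFS[("policy_reval", size)]
    base = _goal_world(load_map(cfg["map"]))
    for lab in ("S1", "S2", "R1", "R2"):
        _label(base, lab)
    s1, s2 = base.state("S1"), base.state("S2")
    result = TaskResult("policy_reval", "S1", base)
    for run_seed in _run_seeds(seed, n_runs):
        rng = random.Random(run_seed)
        agent = agent_factory(base)
        # entire latent-learning procedure with S1 as the start
        _explore(agent, base, s1, cfg["explore"], rng)
        world = base.set_reward("R1", 10.0)
        _probes(agent, world, world.state("R1"), 20, rng)
        # trials alternately starting at S1 / S2, ending at a goal
        for t in range(20):
            _, capped = _trial(agent, world, s1 if t % 2 == 0 else s2, rng)
            result.capped_trials += capped
        world = world.set_reward("R2", 20.0)
        _probes(agent, world, world.state("R2"), 20, rng)
        result.value_tables.append(agent.value_table(world))
        result.run_seeds.append(run_seed)
        result.world = world
    return result


def run_acquisition(agent_factory, n_trials: int, n_runs: int, seed: int,
                    map_name: str = "acquisition",
                    trial_cap: int = TRIAL_CAP) -> TaskResult:
    """Acquisition experiment: repeated trials S -> R with no exploration.

    R carries reward 10 from the first trial on; the record is the
    steps-per-trial curve of each run.
    """
    base = _goal_world(load_map(map_name)).set_reward("R", 10.0)
    start = base.state(_label(base, "S", "S1"))
    result = TaskResult("acquisition", "S", base)
    for run_seed in _run_seeds(seed, n_runs):
        rng = random.Random(run_seed)
        agent = agent_factory(base)
        lengths = []
        for _ in range(n_trials):
            n, capped = _trial(agent, base, start, rng, cap=trial_cap)
            result.capped_trials += capped
            lengths.append(n)
        result.trial_lengths.append(lengths)
        result.run_seeds.append(run_seed)
    return result


#: Reduced parameter lattice for per-variant selection in the acquisition
#: comparisons (the supplementary experiments pick, per algorithm and
#: condition, the setting minimizing total steps before comparing curves).
ACQUISITION_GRID = {
    "alpha_w": (0.1, 0.3, 0.5),
    "epsilon": (0.1, 0.3, 0.5),
}


def acquisition_param_search(agent_name: str, base_params, grid=None,
                             n_trials: int = 20, n_runs: int = 10,
                             seed: int = 0,
                             search_cap: int = 2000):
    """Pick the lattice point minimizing mean total steps over the trials.

    Mirrors the supplementary comparisons' procedure: each variant is
    compared at its own best parameter setting, found by a coarse grid
    search (short capped runs), so a variant is never penalized for a
    learning rate that happens to destabilize it.
    Returns (best AgentParams, search table).
    """
    import dataclasses
    import itertools

    from .agents import make_agent

    grid = dict(ACQUISITION_GRID if grid is None else grid)
    names = list(grid)
    table = []
    best = None
    for values in itertools.product(*(grid[n] for n in names)):
        params = dataclasses.replace(base_params, **dict(zip(names, values)))
        res = run_acquisition(lambda w: make_agent(agent_name, w, params),
                              n_trials, n_runs, seed, trial_cap=search_cap)
        total = float(np.sum(res.trial_lengths)) / n_runs
        table.append({**dict(zip(names, values)), "total_steps": total})
        if best is None or total < best[0]:
            best = (total, params)
    return best[1], table


_TASK_RUNNERS = {
    "latent": run_latent_learning,
    "detour": run_detour,
    "policy_reval": run_policy_revaluation,
}


def run_task(task: str, agent_factory, n_runs: int, seed: int,
             size: str = "full") -> TaskResult:
    """Run one of the three named revaluation tasks."""
    if task not in _TASK_RUNNERS:
        raise ProtocolError(f"unknown task {task!r}; known: {TASK_NAMES}")
    return _TASK_RUNNERS[task](agent_factory, n_runs, seed, size=size)
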