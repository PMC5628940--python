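"""The five agent architectures as stateful policies over a GridWorld.

All agents choose among the *actually available* actions of their current
state with an epsilon-greedy rule over their own Q estimate, and draw every
random number from the single per-run generator the protocol passes in, so a
run is bit-reproducible given (seed, configuration).

Architectures
-------------
``onestep_td``
    Punctate TD learning of V plus a single step of lookahead to form Q —
    the model-free(ish) foil.
``sr_td``
    The original successor representation: TD-learned occupancy matrix M
    and linear reward weights w, V = M w.
``sr_mb``
    Model-based recomputation of M: learns its policy pi and the available
    action sets A_s from experience, rebuilds T^pi before each choice and
    solves M = (I - gamma T)^-1. The transition *physics* is known a priori.
``sr_dyna``
    State-action successor matrix H learned on-policy online (SARSA-style)
    and re-learned *off-policy* by replaying stored samples with a greedy
    continuation; SARSA-TD weights decode Q = H w.
``dyna_q``
    Tabular Q-learning with the same replay schedule — the classic Dyna
    foil, carrying no predictive state representation.

The Dyna agents replay ``n_replay_per_step`` samples after every real step
and a burst of ``k_post_change`` samples whenever a transition contradicts
the last recorded observation of reward or action availability for the
state(-action) involved — the agent has just *learned about a change*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, floor, log

import numpy as np

from .gridworld import (
    COLLECT, N_ACTIONS, TERMINAL, GridWorld, Transition,
)
from . import sr_core
from .sr_core import (
    h_offpolicy_replay_update, h_online_update, q_from_h, sa_index,
    sr_td_update, td_error, value_from_sr, weight_update_direct,
    weight_update_td,
)

AGENT_NAMES = ("onestep_td", "sr_td", "sr_mb", "sr_dyna", "dyna_q")

#: Decay rate of the exponential recency weighting over replay ranks.
REPLAY_LAMBDA = 1.0 / 5.0


@dataclass(frozen=True)
class AgentParams:
    """Learning parameters shared across architectures.

    Defaults are the standard simulation settings: discount gamma = 0.95,
    epsilon-greedy exploration 0.1, weight / occupancy / Q learning rates
    0.3 and policy learning rate 0.1.
    """

    gamma: float = 0.95
    epsilon: float = 0.1
    alpha_w: float = 0.3
    alpha_sr: float = 0.3
    alpha_q: float = 0.3
    alpha_pi: float = 0.1
    n_replay_per_step: int = 0
    k_post_change: int = 0
    weight_norm: str = "normalized"   # normalized | plain  (LMS scaling)
    weight_learning: str = "td"       # td | direct (delta rule on reward)

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        for name in ("alpha_w", "alpha_sr", "alpha_q", "alpha_pi"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------
# selection and update primitives (unit-testable in isolation)
# ---------------------------------------------------------------------------

def epsilon_greedy(q_row, epsilon, rng, actions=None):
    """Epsilon-greedy choice among available actions.

    With probability 1 - epsilon picks the argmax of ``q_row`` (ties broken
    uniformly); otherwise picks uniformly among *all* available actions,
    including the argmax. Returns the entry of ``actions`` (default: the
    index into ``q_row``).
    """
    k = len(q_row)
    if k == 0:
        raise ValueError("no available actions")
    if actions is None:
        actions = range(k)
    if k == 1:
        return actions[0]
    if rng.random() < epsilon:
        return actions[rng.randrange(k)]
    m = max(q_row)
    best = [i for i, v in enumerate(q_row) if v == m]
    i = best[0] if len(best) == 1 else best[rng.randrange(len(best))]
    return actions[i]


def onestep_lookahead_q(V, world: GridWorld, s: int):
    """Q over available actions by one step of lookahead: Q(s,a) = V(s').

    Collect maps to the terminal continuation V = 0 (valid because rewards
    are paired exclusively with terminal-leading actions).
    """
    acts = world.available_actions(s)
    succ = world.successors
    return [0.0 if a == COLLECT else float(V[succ[s, a]]) for a in acts], acts


def srmb_policy_update(pi_row: np.ndarray, chosen: int,
                       alpha_pi: float) -> np.ndarray:
    """Delta-rule policy update toward the chosen cardinal action slot."""
    pi_row *= (1.0 - alpha_pi)
    pi_row[chosen] += alpha_pi
    return pi_row


def srmb_transition_row(pi_row, believed_avail, physics_succ, n_states):
    """One believed-transition row: pi renormalized over available actions.

    ``believed_avail`` holds the cardinal actions the agent currently thinks
    are available; a collect-only state yields an all-zero row (its mass
    exits to the terminal pseudo-state).
    """
    row = np.zeros(n_states)
    acts = [a for a in believed_avail if a != COLLECT]
    z = sum(pi_row[a] for a in acts)
    if not acts:
        return row
    if z <= 0.0:
        raise ValueError("zero renormalizer in believed policy")
    for a in acts:
        row[physics_succ[a]] += pi_row[a] / z
    return row


def dynaq_update(Q: np.ndarray, sample, alpha_q: float, gamma: float,
                 next_actions) -> np.ndarray:
    """Q-learning backup of one (s, a, r, s') sample.

    The continuation is the max over the actions *currently available* in
    s'; terminal successors (and blocked cells, whose action set is empty)
    contribute zero.
    """
    s, a, r, s_next = sample
    if s_next == TERMINAL or not next_actions:
        cont = 0.0
    else:
        cont = max(Q[s_next, an] for an in next_actions)
    Q[s, a] += alpha_q * (r + gamma * cont - Q[s, a])
    return Q


# ---------------------------------------------------------------------------
# experience buffer and recency-weighted replay draws
# ---------------------------------------------------------------------------

class ExperienceBuffer:
    """Append-only store of experienced (s, a, r, s') samples.

    Step stamps are the append positions (strictly increasing); samples are
    additionally indexed by state-action for the uniform-state-action replay
    scheme.
    """

    def __init__(self):
        self.samples: list[Transition] = []
        self.by_sa: dict[tuple[int, int], list[int]] = {}
        self.sa_keys: list[tuple[int, int]] = []

    def __len__(self):
        return len(self.samples)

    def append(self, tr: Transition) -> int:
        i = len(self.samples)
        self.samples.append(tr)
        key = (tr.s, tr.a)
        lst = self.by_sa.get(key)
        if lst is None:
            self.by_sa[key] = [i]
            self.sa_keys.append(key)
        else:
            lst.append(i)
        return i


def _truncated_geometric_rank(n: int, rng, lam: float = REPLAY_LAMBDA) -> int:
    """Draw rank j in [0, n) with P(j) proportional to exp(-lam * j)."""
    if n == 1:
        return 0
    q = exp(-lam)
    x = rng.random() * (1.0 - q ** n)
    j = int(floor(log(1.0 - x) / (-lam)))
    return min(j, n - 1)


def draw_replay_samples(buffer: ExperienceBuffer, count: int, scheme: str,
                        rng, lam: float = REPLAY_LAMBDA) -> list[Transition]:
    """Draw ``count`` stored samples with replacement for replay.

    ``per_step``: exponential recency weighting over the whole buffer
    (most recent first, P(rank j) ~ exp(-lam j)).
    ``post_change``: first a state-action uniformly among those experienced,
    then the same exponential recency weighting within that state-action's
    samples.
    """
    n = len(buffer)
    if n == 0:
        import logging
        logging.getLogger(__name__).warning("empty replay buffer")
        return []
    out = []
    if scheme == "per_step":
        samples = buffer.samples
        for _ in range(count):
            out.append(samples[n - 1 - _truncated_geometric_rank(n, rng, lam)])
    elif scheme == "post_change":
        keys = buffer.sa_keys
        for _ in range(count):
            lst = buffer.by_sa[keys[rng.randrange(len(keys))]]
            m = len(lst)
            out.append(buffer.samples[
                lst[m - 1 - _truncated_geometric_rank(m, rng, lam)]])
    else:
        raise ValueError(f"unknown replay scheme {scheme!r}")
    return out


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class BaseAgent:
    """Common machinery: placement, observation memory, change detection."""

    name = "base"

    def __init__(self, world: GridWorld, params: AgentParams):
        self.params = params
        self.n_states = world.n_states
        self.s: int | None = None
        self._seen_avail: dict[int, tuple] = {}
        self._seen_reward: dict[tuple[int, int], float] = {}

    # -- observation / change detection -----------------------------------

    def _observe_avail(self, world: GridWorld, s: int) -> bool:
        """Record availability at s; True if it contradicts the last record."""
        actual = world.available_actions(s)
        prev = self._seen_avail.get(s)
        if prev == actual:
            return False
        self._seen_avail[s] = actual
        return prev is not None

    def _observe_reward(self, s: int, a: int, r: float) -> bool:
        prev = self._seen_reward.get((s, a))
        if prev == r:
            return False
        self._seen_reward[(s, a)] = r
        return prev is not None

    def _on_availability(self, world, s):
        """Hook: sync any internal availability model (SR-MB)."""

    def _on_change(self, world, rng):
        """Hook: react to a learned change (Dyna agents mark a pending
        offline replay burst)."""

    def offline_replay(self, world, rng) -> None:
        """Offline pause (between trials / after a probe phase).

        Dyna agents run their k_post_change replay burst here if a learned
        change was experienced since the last pause; other agents do
        nothing.
        """

    # -- protocol interface ------------------------------------------------

    def place(self, world: GridWorld, s: int, rng) -> None:
        """Put the agent at state s (episode start or forced probe).

        The agent observes the available actions of the cell it finds
        itself in; a contradicted observation counts as a learned change.
        """
        self.s = s
        self._clear_pending()
        changed = self._observe_avail(world, s)
        self._on_availability(world, s)
        if changed:
            self._on_change(world, rng)

    def _clear_pending(self):
        """Drop any committed next action (episode boundary)."""

    def step(self, world: GridWorld, rng) -> Transition:
        raise NotImplementedError

    def value_table(self, world: GridWorld) -> np.ndarray:
        raise NotImplementedError

    # shared post-transition bookkeeping
    def _after_transition(self, world, tr: Transition, rng) -> None:
        changed = self._observe_reward(tr.s, tr.a, tr.r)
        if tr.s_next != TERMINAL:
            if self._observe_avail(world, tr.s_next):
                changed = True
            self._on_availability(world, tr.s_next)
            self.s = tr.s_next
        else:
            self.s = None
        if changed:
            self._on_change(world, rng)


class OneStepTDAgent(BaseAgent):
    """TD(0) on punctate state values with one step of model lookahead."""

    name = "onestep_td"

    def __init__(self, world, params):
        super().__init__(world, params)
        self.V = np.zeros(world.n_states)

    def step(self, world, rng):
        p = self.params
        s = self.s
        q, acts = onestep_lookahead_q(self.V, world, s)
        a = epsilon_greedy(q, p.epsilon, rng, acts)
        tr = world.step(s, a)
        v_next = 0.0 if tr.s_next == TERMINAL else self.V[tr.s_next]
        self.V[s] += p.alpha_w * td_error(tr.r, p.gamma, v_next, self.V[s])
        self._after_transition(world, tr, rng)
        return tr

    def value_table(self, world):
        return self.V.copy()


class SRTDAgent(BaseAgent):
    """Original SR: TD-learned occupancy matrix M plus linear weights w."""

    name = "sr_td"

    def __init__(self, world, params):
        super().__init__(world, params)
        n = world.n_states
        self.M = np.eye(n)
        self.w = np.zeros(n)
        self._w_live = False  # fast path while no reward has been seen

    def _values(self):
        if not self._w_live:
            return None  # identically zero
        return value_from_sr(self.M, self.w)

    def step(self, world, rng):
        p = self.params
        s = self.s
        V = self._values()
        if V is None:
            acts = world.available_actions(s)
            a = acts[rng.randrange(len(acts))] if len(acts) > 1 else acts[0]
        else:
            q, acts = onestep_lookahead_q(V, world, s)
            a = epsilon_greedy(q, p.epsilon, rng, acts)
        tr = world.step(s, a)
        term = tr.s_next == TERMINAL
        if V is None:
            v_cur = v_next = 0.0
        else:
            v_cur = float(V[s])
            v_next = 0.0 if term else float(V[tr.s_next])
        delta = td_error(tr.r, p.gamma, v_next, v_cur)
        if delta != 0.0 or self._w_live:
            if p.weight_learning == "direct":
                weight_update_direct(self.w, s, tr.r, p.alpha_w)
            else:
                weight_update_td(self.w, self.M[s].copy(), delta,
                                 p.alpha_w, p.weight_norm)
            self._w_live = self._w_live or bool(np.any(self.w))
        sr_td_update(self.M, s, tr.s_next, p.alpha_sr, p.gamma)
        self._after_transition(world, tr, rng)
        return tr

    def value_table(self, world):
        V = self._values()
        return np.zeros(self.n_states) if V is None else V


class SRMBAgent(BaseAgent):
    """Model-based SR: recompute M = (I - gamma T^pi)^-1 before each choice.

    The agent knows the maze physics (which cell each available move leads
    to) but learns which actions are available (A_s) and its own empirical
    policy pi from experience; reward knowledge lives only in w.
    """

    name = "sr_mb"

    def __init__(self, world, params):
        super().__init__(world, params)
        n = world.n_states
        # physics of the *original* maze; availability changes are tracked
        # in the believed availability mask, not here.
        self._physics = world.successors.copy()
        self.avail_cardinal = np.zeros((n, 4), dtype=bool)
        self.collect_only = np.zeros(n, dtype=bool)
        for s in range(n):
            acts = world.available_actions(s)
            if acts == (COLLECT,):
                self.collect_only[s] = True
            else:
                for a in acts:
                    self.avail_cardinal[s, a] = True
        self.pi = np.full((n, 4), 0.25)
        self.w = np.zeros(n)
        self._w_live = False

    def _on_availability(self, world, s):
        acts = world.available_actions(s)
        if acts == (COLLECT,):
            self.collect_only[s] = True
            self.avail_cardinal[s] = False
        else:
            self.collect_only[s] = False
            row = np.zeros(4, dtype=bool)
            for a in acts:
                row[a] = True
            self.avail_cardinal[s] = row

    def transition_matrix(self) -> np.ndarray:
        """Believed one-step matrix T^pi over states (zero rows absorb)."""
        n = self.n_states
        w = np.where(self.avail_cardinal, self.pi, 0.0)
        z = w.sum(axis=1)
        live = z > 0
        w[live] /= z[live, None]
        w[~live] = 0.0
        T = np.zeros((n, n))
        rows = np.repeat(np.arange(n), 4)
        cols = self._physics[:, :4].ravel()
        vals = w.ravel()
        ok = (cols >= 0) & (vals > 0)
        np.add.at(T, (rows[ok], cols[ok]), vals[ok])
        return T

    def successor_matrix(self) -> np.ndarray:
        return sr_core.successor_from_transition(
            self.transition_matrix(), self.params.gamma)

    def step(self, world, rng):
        p = self.params
        s = self.s
        M = V = None
        if self._w_live:
            M = self.successor_matrix()
            V = value_from_sr(M, self.w)
            q, acts = onestep_lookahead_q(V, world, s)
            a = epsilon_greedy(q, p.epsilon, rng, acts)
        else:
            acts = world.available_actions(s)
            a = acts[rng.randrange(len(acts))] if len(acts) > 1 else acts[0]
        tr = world.step(s, a)
        term = tr.s_next == TERMINAL
        if tr.r != 0.0 or self._w_live:
            if M is None:
                M = self.successor_matrix()
                V = value_from_sr(M, self.w)
            v_next = 0.0 if term else float(V[tr.s_next])
            delta = td_error(tr.r, p.gamma, v_next, float(V[s]))
            weight_update_td(self.w, M[s], delta, p.alpha_w, p.weight_norm)
            self._w_live = self._w_live or bool(np.any(self.w))
        if a != COLLECT:
            srmb_policy_update(self.pi[s], a, p.alpha_pi)
        self._after_transition(world, tr, rng)
        return tr

    def value_table(self, world):
        if not self._w_live:
            return np.zeros(self.n_states)
        return value_from_sr(self.successor_matrix(), self.w)


class _DynaMixin:
    """Replay schedule shared by SR-Dyna and Dyna-Q.

    A learned change (contradicted reward or availability observation)
    marks a burst of ``k_post_change`` replays as pending; the burst runs at
    the next offline pause — the end of the trial or probe phase in which
    the change was experienced — once the agent's local knowledge of the
    change (recent samples, updated weights) is in place.
    """

    _change_pending = False

    def _replay_one(self, world, tr: Transition, rng):
        raise NotImplementedError

    def _replay(self, world, rng, count, scheme):
        if count <= 0 or len(self.buffer) == 0:
            return
        for tr in draw_replay_samples(self.buffer, count, scheme, rng):
            self._replay_one(world, tr, rng)

    def _on_change(self, world, rng):
        self._change_pending = True

    def offline_replay(self, world, rng):
        if self._change_pending:
            self._change_pending = False
            self._replay(world, rng, self.params.k_post_change,
                         "post_change")


class SRDynaAgent(_DynaMixin, BaseAgent):
    """SR over state-actions with off-policy replay of stored samples.

    Online behaviour is on-policy: H rows are updated toward the state-action
    actually taken next (SARSA-style), and w by the SARSA TD error. Replay
    re-learns H toward the *greedy* continuation under the current w, which
    is what buys model-based flexibility given enough samples.
    """

    name = "sr_dyna"

    def __init__(self, world, params):
        super().__init__(world, params)
        nsa = world.n_states * N_ACTIONS
        self.H = np.eye(nsa)
        self.w = np.zeros(nsa)
        self.buffer = ExperienceBuffer()
        self._w_live = False
        self._next_a: int | None = None

    def _clear_pending(self):
        self._next_a = None

    def _choose(self, world, s, rng):
        acts = world.available_actions(s)
        if len(acts) == 1:
            return acts[0]
        if not self._w_live:
            return acts[rng.randrange(len(acts))]
        idx = [sa_index(s, a) for a in acts]
        q = self.H[idx] @ self.w
        return epsilon_greedy(list(q), self.params.epsilon, rng, acts)

    def _q(self, sa):
        return float(self.H[sa] @ self.w) if self._w_live else 0.0

    def step(self, world, rng):
        p = self.params
        s = self.s
        a = self._next_a if self._next_a is not None \
            else self._choose(world, s, rng)
        self._next_a = None
        tr = world.step(s, a)
        sa = sa_index(s, a)
        term = tr.s_next == TERMINAL
        if term:
            sa_next = TERMINAL
        else:
            a2 = self._choose(world, tr.s_next, rng)
            sa_next = sa_index(tr.s_next, a2)
            self._next_a = a2
        # SARSA weight step (before the H row moves, so features are the
        # occupancies the error was computed under)
        if tr.r != 0.0 or self._w_live:
            if p.weight_learning == "direct":
                weight_update_direct(self.w, sa, tr.r, p.alpha_w)
            else:
                cont = 0.0 if term else self._q(sa_next)
                delta = td_error(tr.r, p.gamma, cont, self._q(sa))
                weight_update_td(self.w, self.H[sa].copy(), delta,
                                 p.alpha_w, p.weight_norm)
            self._w_live = self._w_live or bool(np.any(self.w))
        h_online_update(self.H, sa, sa_next, p.alpha_sr, p.gamma)
        self.buffer.append(tr)
        self._replay(world, rng, p.n_replay_per_step, "per_step")
        self._after_transition(world, tr, rng)
        return tr

    def _replay_one(self, world, tr, rng):
        if tr.s_next == TERMINAL or world.blocked[tr.s_next]:
            cands = ()
        else:
            cands = [sa_index(tr.s_next, a)
                     for a in world.available_actions(tr.s_next)]
        sa = sa_index(tr.s, tr.a)
        if not self._w_live and len(cands) > 1:
            # all Q equal: the greedy tie is a uniform draw, skip the dots
            h_online_update(self.H, sa, cands[rng.randrange(len(cands))],
                            self.params.alpha_sr, self.params.gamma)
            return
        h_offpolicy_replay_update(self.H, self.w, sa, cands,
                                  self.params.alpha_sr, self.params.gamma,
                                  rng)

    def q_table(self):
        return q_from_h(self.H, self.w).reshape(self.n_states, N_ACTIONS)

    def value_table(self, world):
        Q = self.q_table()
        V = np.zeros(self.n_states)
        for s in range(self.n_states):
            acts = world.available_actions(s)
            if acts:
                V[s] = max(Q[s, a] for a in acts)
        return V


class DynaQAgent(_DynaMixin, BaseAgent):
    """Tabular Q-learning with recency-weighted experience replay."""

    name = "dyna_q"

    def __init__(self, world, params):
        super().__init__(world, params)
        self.Q = np.zeros((world.n_states, N_ACTIONS))
        self.buffer = ExperienceBuffer()

    def _backup(self, world, tr: Transition):
        if tr.s_next == TERMINAL or world.blocked[tr.s_next]:
            next_acts = ()
        else:
            next_acts = world.available_actions(tr.s_next)
        dynaq_update(self.Q, (tr.s, tr.a, tr.r, tr.s_next),
                     self.params.alpha_q, self.params.gamma, next_acts)

    def step(self, world, rng):
        p = self.params
        s = self.s
        acts = world.available_actions(s)
        q = [self.Q[s, a] for a in acts]
        a = epsilon_greedy(q, p.epsilon, rng, acts)
        tr = world.step(s, a)
        self._backup(world, tr)
        self.buffer.append(tr)
        self._replay(world, rng, p.n_replay_per_step, "per_step")
        self._after_transition(world, tr, rng)
        return tr

    def _replay_one(self, world, tr, rng):
        self._backup(world, tr)

    def value_table(self, world):
        V = np.zeros(self.n_states)
        for s in range(self.n_states):
            acts = world.available_actions(s)
            if acts:
                V[s] = max(self.Q[s, a] for a in acts)
        return V


_AGENT_CLASSES = {
    "onestep_td": OneStepTDAgent,
    "sr_td": SRTDAgent,
    "sr_mb": SRMBAgent,
    "sr_dyna": SRDynaAgent,
    "dyna_q": DynaQAgent,
}


def make_agent(name: str, world: GridWorld,
               params: AgentParams | None = None) -> BaseAgent:
    """Construct a fresh agent of the given architecture for a world."""
    if name not in _AGENT_CLASSES:
        raise ValueError(f"unknown agent {name!r}; known: {AGENT_NAMES}")
    return _AGENT_CLASSES[name](world, params or AgentParams())


def agent_step(agent: BaseAgent, world: GridWorld, s: int, rng) -> Transition:
    """Single environment step of an agent from state s (dispatch helper)."""
    if agent.s != s:
        agent.place(world, s, rng)
    return agent.step(world, rng)
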