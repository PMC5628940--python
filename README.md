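# srgrid

Tabular reinforcement-learning agents built around the **successor
representation (SR)**, together with the gridworld revaluation tasks that
expose how much model-based flexibility each architecture actually has.
Intended for computational-neuroscience and RL researchers who want a
reproducible reference implementation of the SR agent family and its
categorical behavioural signatures.

## The science

A decision maker that caches long-run values (model-free TD learning)
cannot react to a distal change in reward or maze structure without
relearning; full model-based planning (value iteration over a one-step
model) reacts immediately but is computationally heavy at choice time. The
SR sits between the two: it caches the matrix of discounted expected future
state occupancies under the behaviour policy,

    M^π(s, s') = E_π [ Σ_t γ^t 1(s_t = s') | s_0 = s ],

so that values decompose linearly into a predictive map and a reward
vector,

    V^π(s) = Σ_s' M^π(s, s') w(s'),      w(s') ≈ Σ_a π(a|s') R(s', a),

with M satisfying M = (I − γT^π)^−1 for the policy's one-step transition
matrix T^π. Which behaviours this buys depends on how M is maintained:

| agent | M / Q maintenance | latent learning | detour | policy revaluation |
|---|---|---|---|---|
| `onestep_td` | none (punctate V, 1-step lookahead) | ✗ | ✗ | ✗ |
| `sr_td` | TD-learned M (cached rows) | ✓ | ✗ | ✗ |
| `sr_mb` | M recomputed from learned T^π at choice time | ✓ | ✓ | ✗ |
| `sr_dyna` (k=10000) | state-action SR, off-policy replay of stored samples | ✓ | ✓ | ✓ |
| `sr_dyna` (k=10) | insufficient replay | ✓ | ✗ | ✗ |
| `dyna_q` (k=10000) | tabular Q + replay | ✓ | ✓ | ✓ |
| `dyna_q` (k=10) | insufficient replay | ✗ | ✗ | ✗ |

The three tasks stage a *local* change — a newly rewarded cell (latent
learning), a barrier (detour), a larger reward off the habitual paths
(policy revaluation) — and ask whether the agent's value function
immediately implies the globally optimal policy, with no retraining from
the start state. Verdicts are computed from the median value map over
independent runs: each open cell points at its highest-valued accessible
neighbor, and the policy passes iff it reaches the best reward from the
start in exactly the shortest-path number of steps. See
[docs/methods.md](docs/methods.md) for the update rules, parameters, replay
schedule, and numerical choices.

## Worked example

```python
from srgrid import AgentParams, make_agent, run_task
from srgrid.analysis import median_value_map, implied_policy, policy_optimal

result = run_task("latent", lambda w: make_agent("sr_td", w, AgentParams()),
                  n_runs=20, seed=42, size="small")
vmap = median_value_map(result)
world = result.world
print("median value at R1:", round(vmap[world.state("R1")], 3))
print("median value at S: ", round(vmap[world.state("S")], 3))
pmap = implied_policy(vmap, world)
print("policy optimal from S:", policy_optimal(pmap, world, "S"))
```

prints

```
median value at R1: 9.992
median value at S:  0.027
policy optimal from S: True
```

The value at the rewarded cell is 10·(1 − 0.7²⁰) ≈ 9.992 — twenty collect
probes at learning rate 0.3 — and the small but positive value at the start
cell S is the point of the experiment: the agent was *never rewarded on any
trajectory from S*, yet its cached occupancy map decodes the new reward
into a gradient whose implied policy walks the shortest path to R1. The
same probe experience leaves a one-step-lookahead TD agent
(`make_agent("onestep_td", ...)`) with value zero everywhere except R1
itself, and its implied policy fails.

The command line exposes the same pipeline:

```bash
srgrid run-task --task latent --agent sr_td --runs 100 --seed 1 --out results/
srgrid flex-matrix --runs 500 --seed 1 --out results/      # full-scale, slow
srgrid sweep --param alpha_sr=0.1,0.3,0.9 --runs 100 --seed 1 --size small
srgrid render --task detour --agent sr_mb --runs 100 --seed 1   # heatmap
```

`flex-matrix` at the full-scale defaults (10×10 mazes, 500 runs) takes a
long while; `--size small --runs 100` reproduces the same categorical table
in about five minutes.

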