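# Methods

## The model family

All simulations take place in deterministic gridworld Markov decision
processes. Open cells are states; from a non-rewarded cell the agent may move
in the four cardinal directions unless a wall blocks the move (a blocked move
is *unavailable*, not a no-op — agents select among available actions only).
A rewarded cell exposes a single `collect` action that pays the cell's reward
magnitude and leads to an absorbing terminal pseudo-state. Reward cells exist
as zero-reward absorbing goals from the start of every task; the task
manipulations *raise* their magnitude. Whenever the agent absorbs, the
protocol teleports it back to the current phase's start cell.

Values are discounted expected cumulative reward,
V^π(s) = E_π[Σ_t γ^t r_t | s_0 = s], with γ = 0.95 throughout. The package
centers on the successor representation (SR): the matrix of discounted
expected future state occupancies

    M^π(s, s') = E_π[Σ_t γ^t 1(s_t = s') | s_0 = s],

which factors value computation into a policy-dependent predictive map and a
reward vector, V = M w, where the converged w(s') is the policy-averaged
one-step reward in s'. M solves M = I + γ T^π M for the one-step policy
matrix T^π, equivalently M = (I − γT^π)^−1 or the Neumann series
Σ_n γ^n (T^π)^n. The state-action analogue H over (s, a) pairs decodes
action values directly, Q = H w.

### Agents

* **onestep_td** — punctate TD(0) on V plus one step of lookahead to form Q
  (`Q(s,a) = V(s')`); the depth-one foil. Omitting the immediate reward from
  the lookahead is exact here because rewards are paired only with
  terminal-leading actions.
* **sr_td** — the original SR: M learned by the TD-like row update
  `M(s,:) ← M(s,:) + α_sr [1_s + γ M(s',:) − M(s,:)]` after each transition,
  with w learned by linear TD on the features M(s,:). M is initialized to
  the identity; the terminal pseudo-state contributes a zero continuation
  row, so a reward state's own row converges to its one-hot (occupy self
  once, then exit), which is its exact value.
* **sr_mb** — model-based recomputation: the agent knows the maze *physics*
  (which cell each available move would lead to) and learns (i) the
  availability sets A_s of the states it visits and (ii) its own empirical
  policy π(a|s) by a delta rule toward chosen actions. Before each choice it
  assembles T^π — rows renormalized over believed-available actions, zero
  rows for collect-only states — and solves M = (I − γT^π)^−1 by matrix
  inversion (the series form is equivalent). Weight learning and Q
  formation are as in sr_td. Reward information never enters the
  construction of M; that serial staging is what makes the model on-policy
  and is the source of its policy-revaluation failure.
* **sr_dyna** — state-action SR. Online behaviour is on-policy: H rows move
  toward the state-action actually taken next, and w follows the SARSA TD
  error with features H(sa,:). Every sample (s, a, s') is stored; after each
  step the agent replays `n_replay_per_step` samples, and a burst of
  `k_post_change` samples follows any experienced change (see below).
  Replayed updates are *off-policy*: the continuation row belongs to the
  greedy action at s' under the current w, ties broken uniformly.
* **dyna_q** — tabular Q-learning with the same storage and replay schedule;
  the classic replay foil carrying no predictive representation.

### Parameters

| name | meaning | default |
|---|---|---|
| γ | discount | 0.95 |
| ε | exploration probability (ε-greedy) | 0.1 |
| α_w | weight / value learning rate | 0.3 |
| α_sr | occupancy-matrix learning rate | 0.3 |
| α_Q | Dyna-Q learning rate | 0.3 |
| α_π | SR-MB policy learning rate | 0.1 |
| n_replay_per_step | replays after each real step (Dyna agents) | 10 |
| k_post_change | replay burst after a learned change | 10 or 10000 |

Replay draws are recency weighted: rank j (most recent first) has
probability ∝ exp(−j/5). Per-step replay applies this over the whole
buffer; the post-change burst first draws a state-action uniformly among
those experienced, then applies the same recency law within that
state-action's samples. The recency weighting is what lets stale samples
(pre-change rewards, transitions into a now-walled cell) be displaced by
the probe experience.

### Weight-update normalization

The weight step divides by the squared feature norm (normalized LMS),
`w ← w + α_w δ f / (f·f)`, so α_w keeps its meaning as a proportional step
size whatever the scale of an occupancy row; with punctate features this
coincides with the plain rule, which is kept available as a flag
(`weight_norm="plain"`). The same normalization is applied to SR-Dyna's
SARSA weight step: α_w‖H(sa,:)‖² can exceed the LMS stability bound, and
the proportional-step rationale applies to any feature row. All-zero
feature rows skip the update.

### Change detection and offline replay timing

Agents record, per state, the available actions they observe (on every
arrival and every placement) and, per state-action, the realized reward. A
transition or placement that contradicts the last record is a *learned
change*. For Dyna agents it marks the k_post_change burst as pending; the
burst runs at the next offline pause — the end of the trial or probe phase
in which the change was experienced. Running it at the first contradicting
transition instead would launch 10000 backups while a single stored sample
carries the new reward, and the recency-weighted draw would propagate a
source value still dominated by stale samples; deferring to the phase
boundary (replay as an off-line, between-trials process) lets the probe
experience accumulate first. Per-step replay is unaffected and runs
throughout.

During replay, the greedy/max continuation at a sample's successor state is
taken over the actions currently available there; an empty set (the
successor became a wall) or a terminal successor contributes zero. Bursts
only run after the change has been experienced, so this gives the agent
nothing it has not observed.

## Task protocols

Three procedures, each a pure function of (fixture, agent config, seed),
recorded as the agent's value table at the probe point (for Q-based agents,
the per-state max available action value):

* **Latent learning** — exploration from S (25000 steps at full scale),
  reward at R1 raised to 10, experienced only by 20 single-step collect
  probes from R1; record.
* **Detour** — exploration (10000 steps), reward at R raised to 10, 5
  trials from S, a wall inserted at B (which keeps its state index with an
  empty action set, so matrices never resize), experienced only by 40
  single-step probes from the cell immediately west of B; record. The
  fixture validator requires B to lie on a shortest trained S→R path.
* **Policy revaluation** — the full latent procedure (S1 as start), 20
  trials alternating S1/S2 that end at any absorbing goal, reward at R2 set
  to 20, 20 single-step probes from R2; record.

The acquisition experiment (no exploration phase) runs repeated trials from
S to a rewarded R on a hallway maze and records steps per trial; a
10^6-step cap flags non-terminating episodes.

## Analysis

Per-state **median** value over runs (lower median for even run counts,
fixed for bit-reproducibility) → **implied policy** (each open cell points
at its highest-valued accessible neighbor; near-equal maxima within 1e−9
are tie-flagged) → **verdict**: pass iff greedily following the implied
policy from the task's start reaches the maximal-reward cell in exactly the
BFS shortest-path number of steps with no tie-flagged cell en route. A
tie on the trajectory fails rather than being resolved randomly — optimal
means definitely optimal. Bellman value iteration over available actions
(tolerance 1e−10) provides the fully model-based oracle.

## Fixtures and problem sizes

The exact published maze layouts are not available as data; the bundled
10×10 fixtures reproduce their topological structure — spiral hallways for
latent learning, a blocked main corridor with one alternate route for the
detour, twin starts funnelling to a middle reward with a larger reward in
the far bottom-right corner for policy revaluation (distances satisfy
γ^d(R2)·20 > γ^d(R1)·10 from S1, so the optimal goal is unambiguous). The
categorical results are robust to layout and scale, and the test suite and
acceptance script run 7-wide variants of the same topologies with
exploration lengths scaled to preserve visits-per-state density (6000 /
2500 / 6000 steps) and 100 runs per combination; the full-scale protocol
(500 runs) remains the default for the CLI. Median-based verdicts are
already stable at 100 runs.

What the synthetic mazes do not emulate: stochastic transitions, sensory
aliasing, continuous space, or any vicarious/real replay dynamics — a pass
here shows a property of the algorithms' representations, not a fit to
animal trajectories.

## Acquisition comparisons

The replay (20 vs 0 replays per decision) and weight-learning (TD vs
direct delta rule on immediate reward) comparisons follow the
supplementary procedure of comparing each condition *at its own best
parameters*: a coarse grid over α_w × ε ∈ {0.1, 0.3, 0.5}² (10 runs of 20
capped trials per point) selects the setting minimizing mean total steps,
and the reported curves are 100 fresh runs at that setting. This matters:
TD weight learning over evolving occupancy features is markedly faster
early but destabilizes at large α_w once the policy (and hence M) becomes
near-deterministic — value overestimates create transient greedy traps —
so comparing both variants at one fixed learning rate would measure the
instability, not the representational question.

## Numerical choices

* Series truncation N = 500 (γ^500 ≈ 7·10⁻¹²), below every test tolerance.
* Greedy/argmax ties anywhere in an agent are broken uniformly with the
  run's single seeded generator; runs are bit-reproducible given
  (seed, config).
* Even-run-count medians use the lower median.
* Value-iteration oracle tolerance 1e−10; oracle action ties use a 1e−9
  margin.
* The TD-learned occupancy matrix at a constant step size α retains
  stationary sampling noise of order √α times the entry scale; at α = 0.01
  on a 4×4 open grid the largest entry error across 256 entries sits around
  0.07–0.14 however long the walk runs. Driving it lower requires either a
  decaying step size or iterate averaging, neither of which the online
  agents use.

## Known limitations

* SR-MB's believed availability is initialized to the original maze's true
  availability (the agent is granted the physics of legal moves a priori);
  only subsequent changes — the inserted barrier, reward
  introductions — must be discovered from experience. After the long
  exploration phases this is indistinguishable from starting with all four
  actions believed available everywhere.
* Tabular representations only: no function approximation, eligibility
  traces, multi-γ spectra, prioritized sweeping, or hidden-state inference.
* The per-step replay "recency-weighted bias" is given the same exponential
  law (λ = 1/5) as the post-change draw, applied over the whole buffer; no
  other distribution is specified anywhere.
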