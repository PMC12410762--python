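# Methods

## Model

A FEPS agent is a tabular model-based agent for deterministic, partially
observable environments. Its latent space is fixed in advance: each of the
`N_S` observations owns `N_clones` belief clips, giving `N_B = N_S ×
N_clones` clips and a deterministic emission function (clip → its parent
observation). Only the action-conditioned transition weights between clips
are learned: for every action there is an `N_B × N_B` table of non-negative
h-values, normalized row-wise into transition probabilities. Two copies of
the table coexist — behaviour samples from the **prior**, internal rewards
accumulate in the **posterior**, and the prior is overwritten by the
posterior at the end of every episode. This staggering is what makes the
per-step free energy a meaningful learning signal: it compares the updated
belief distribution against the one the agent actually acted from.

### Reinforcement by prediction accuracy

At each step the agent samples its next belief clip from the prior row of
(current clip, chosen action) and predicts the corresponding observation. A
maximal run of correct predictions is a *trajectory*; a run containing no
correct prediction is not a trajectory and does not enter the length
statistics. While a trajectory is open, every distinct edge on it gains one
unit of confidence `f` per verified prediction, so an edge used at verified
step k of a trajectory that ends after L verified steps carries `f = L − k +
1` (an edge recurring inside one trajectory still counts once per step, not
once per occurrence). On the first wrong prediction (or at episode end) the
trajectory closes and each edge receives

    h ← h − γ·(h − h0) + f·R

in the posterior; the final mismatched edge has `f = 0` and only decays.
The forgetting term is applied, at each close, to **every** edge of the
table (`decay_scope="global"`, the default). This choice matters: with
decay restricted to the trajectory's own edges, the losing side of a clone
convention retains its accumulated weight indefinitely and agents never
break the symmetry between clones (we observed 0/20 convergence on the
timed task under any (γ, R) tried; 10/10 with global decay). A
`decay_scope="trajectory"` switch retains the restricted variant.

After a mismatch (and at episode start) the belief resets to a uniformly
random clone of the observed sensory state — the maximum-entropy choice,
which lets all clones compete for every contextual role.

### Free energies

The logged per-step variational free energy is

    F = KL[q(B′|b,a) ‖ p(B′|b,a)] + E_{b′∼q}[ −log p̃(s_env|b′) ]

with q/p the posterior/prior rows actually used and p̃ an ε-smoothed
emission (ε = 10⁻³): the literal deterministic emission gives infinite
surprise whenever posterior mass sits on clones of another observation,
while the smoothing keeps the learning curves finite without affecting any
other computation. F is bounded below by −log(1−ε) ≈ 10⁻³.

The expected free energy of action a from clip b is the negative predicted
belief entropy plus the expected preference surprise; the policy is
`softmax(ζ·G)` row-wise. In exploration mode the preference is the
action-marginal of the model under the previous policy refresh (uniform
initially), for which the EFE reduces identically to the information gain
`KL[p(B′|b,a) ‖ p(B′|b)]` — an identity the test suite checks to 1e-9 on
random models. A positive ζ then drives the agent toward the transitions
its model has not resolved, escaping the trap of hiding wherever
predictions are already easy.

### Preference floors

Zero probabilities inside the EFE's logarithm require a floor, and the
choice turns out to be behaviourally decisive. During training the
look-ahead preference factor is floored at the uniform value `1/N_B`: an
absolute floor such as 1e-12 adds ~27 nats of surprise to every unpreferred
transition, which buries the entropy (epistemic) term of the EFE and makes
the softmax policy effectively greedy at any usable |ζ| — task-trained
agents then lock into the first predictable loop they find (on the timed
task, the degenerate "press immediately" cycle) and never discover the
target. With the uniform floor the utility and entropy terms share a scale,
policies stay soft, and the characteristic ζ orderings emerge on the grid. At
evaluation time the planner collapses each look-ahead row to a point mass
on its best transition; such a row *forbids* the alternatives, so there the
absolute 1e-12 floor applies and the resulting policy is near-greedy at
ζ = −1. The absolute-preference factor is never zero (the non-target mass
is (1−p\*)/(N_S−1)) and keeps the 1e-12 guard only formally.

### Planner

Given a target observation, `infer_policy` runs `k_pref` refinement
iterations starting from the uniform policy: (1) reachability `r(b′|b) =
Σ_a π(a|b)·p(b′|b,a)`; (2) values seeded with each clip's absolute
preference and propagated for `horizon` steps, each clip taking the best of
its previous value and `βⁿ⁻¹·r(b⁺|b)·v(b⁺)` (values never decrease); (3) a
look-ahead preference proportional to the propagated values over the
*children* of b — successors whose reachability strictly exceeds the row
mean (a uniform row has no children and falls back to a uniform
preference); (4) the EFE and softmax with the configured ζ. No environment
handle exists anywhere in this path; changing the target is a pure
recomputation, and the test suite checks the model is bit-identical across
target swaps. During training, the task-mode policy refresh runs one such
iteration per episode, also seeded from the uniform policy: seeding from
the acting policy instead locks the children sets onto transitions the
policy already takes, and the agent oscillates next to the goal without
ever learning the goal's own transitions.

### Superposition belief filter

With aliased observations the correct clone is unknowable from a single
observation, so evaluation tracks *all* compatible clones: each candidate
votes by sampling one action from its policy row (an exact-mixture variant
exists behind a flag), the action is sampled from the vote frequencies,
each candidate samples its own successor (argmax variant behind a flag),
and successors whose observation disagrees with the environment are
eliminated; duplicates merge, and an empty survivor set restarts from all
clones of the current observation. This is a support-only Bayes filter with
a uniform posterior over survivors; on exact models its survivor set equals
the support of an exact deterministic-emission filter, checked against an
independent boolean-matrix implementation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `h0` | 0.1 | initial/resting h-value; with reward scale R it sets row sharpness (dynamics depend only on γ and h0/R) |
| `gamma` | 0.01 | forgetting rate per trajectory close |
| `R` | 1.0 | reward per unit confidence |
| `decay_scope` | `global` | apply forgetting to all edges at each close |
| `zeta` | per run | EFE scaling of the softmax policy |
| `pstar` | 0.95 | absolute preference of the target observation |
| `horizon` | 2 (timed) / 4 (grid) | value-propagation depth ≥ environment diameter |
| `beta` | 0.5 (timed) / 0.9 (grid) | propagation discount |
| `k_pref` | 1 (timed) / 2 (grid) | policy-refinement iterations |
| episode length | 80 steps | both environments |
| window | 100 (timed) / 1500 (grid) episodes | running-average window for logged curves |

The reinforcement constants (h0, γ, R) are not pinned down by the
behavioural protocols; the defaults above were fixed once during development as the
regime in which the method converges reliably on both testbeds, and were
not adjusted afterwards. The grid discount β = 0.9 is likewise a
consequence of the method's structure: with a stronger discount, values
inherited across three or more reachability steps fall below the flat
non-target preference floor and the far corner loses its gradient toward
the goal entirely.

Study conditions follow the behavioural protocols: timed task — 2 clones
per observation, 4000 episodes × 80 steps, 100 agents at full scale (20 at
desk scale); grid — 3 clones, 40000 episodes × 80 steps, 30 agents at full
scale (5 at desk scale). The test suite trains the grid populations at
15000 episodes to stay fast; the acceptance script keeps the full
40000-episode budget with the reduced agent count.

## Implementation notes

The training loop exists twice: a readable reference path composed of the
public operations, and a numba-jitted kernel used by default. Both consume
an identical pre-generated uniform stream (three slots per step — action,
successor, belief-reset; the reset slot is drawn but discarded on a match),
so the two paths produce identical runs for a fixed seed; the equivalence
is asserted in the tests. All randomness derives from one master seed via
per-agent `SeedSequence` spawns, making every run bit-reproducible.

Convergence checks distinguish *converged* (windowed trajectory length ≥
64/80 and windowed VFE < 1) from *appropriate* (the argmax transition
graph, explored as a product automaton against the environment from every
compatible start clone, reproduces the environment's dynamics exactly).
The distinction matters because an agent can converge onto a
self-consistent but wrong model — on the timed task, a cycle that presses
immediately and never visits satiation — whose free energy is minimal yet
from which no planner can reach the goal. Planning-quality guarantees are
therefore stated for appropriate agents only. Duplicate clones (several
clips serving the same hidden state) are a normal outcome when more clones
are available than contexts; the product check accommodates them.

## What the testbeds do and do not show

Both environments are small, deterministic and strongly connected, and the
observation spaces are tiny; passing their tests demonstrates that the
reinforcement mechanism breaks observation aliasing via context, that the
information-gain preference sustains exploration, that one-shot planning
recovers shortest routes from an accurate model, and that superposition
filtering roughly doubles prediction runs over single-clip tracking. It
does not demonstrate scalability (the edge count grows quadratically in the
clone count and the uniform-floored EFE was only examined at N_B ≤ 12),
robustness to stochastic environments (the data model admits them, but no
quantitative claims are tested), or behaviour when the clone budget is
smaller than the number of contexts an observation needs.

## Known limitations

* The anti-exploratory task setting (ζ = +3 on the grid) is reliably the
  worst-performing setting, but it still learns a fair amount (final
  trajectory lengths ≈ 33–42 of 80 across seeds at 5 agents): with bounded
  preference surprises even certainty-seeking agents retain some learning
  drive, and 5-agent means are noisy.
* Trajectory-length curves depend on the belief-reset convention at episode
  starts; excluding zero-length runs from the statistic (a run with no
  correct prediction is not a trajectory) is the reading used throughout.
* The closed-form asymptote of the exploration EFE is not implemented; the
  plateau is asserted only qualitatively (its mid-training slope is small
  relative to the VFE's).
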