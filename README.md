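# feps — Free Energy Projective Simulation

Interpretable, reward-free active-inference agents built on projective
simulation, for computational cognitive science and behavioural modelling.

A FEPS agent learns a **clone-structured world model** of a partially
observable environment using nothing but its own prediction accuracy: each
observation owns a fixed set of *clone clips* (belief states), and the
action-conditioned transition weights between clips — *h-values*, normalized
row-wise into probabilities — are reinforced whenever a sampled transition
correctly predicts the next observation. The confidence `f` of every edge on
the current run of correct predictions grows by one per verified step, and
when a prediction finally fails the run ("trajectory") closes with

```
h  ←  h − γ·(h − h₀) + f·R
```

applied to the posterior transition table; the prior, from which behaviour
samples, is replaced by the posterior at each episode end. Behaviour itself
follows active inference: the policy is a softmax of the **expected free
energy**

```
G_b[a] = −H[B′ | b, a] + E_{b′,s′}[ −log p_ref(s′, b′ | b) ],     π(a|b) = softmax(ζ·G_b)[a]
```

with a scaling parameter ζ (negative = preference-seeking, 0 = uniform,
positive = certainty-seeking). Two preference distributions are supported:
an **exploration** preference (the action-marginal of the model itself, for
which the EFE reduces exactly to the information gain about the next belief
state) and a factorized **task** preference (probability p\* on a target
observation times a look-ahead distribution over belief transitions built by
propagating target value through the model's reachability graph). The
planner infers a goal-directed policy from the trained model in a single
call, without any environment interaction, and a **superposition belief
filter** tracks every clone compatible with the observation history to cope
with aliased observations.

Two behavioural testbeds are built in:

* `timed` — a timed-response conditioning box: wait exactly one step after
  the light turns on, then press the lever to reach satiation (4 hidden
  states, 3 observations, one aliased).
* `grid3` — a 3×3 foraging grid with a smell gradient 0–3 toward food in a
  corner; most smells are emitted by several cells.

## Worked example

Train five agents on the timed-response task with a uniform policy (pure
exploration), then plan toward satiation:

```python
import numpy as np
from feps import RunConfig, train, make_env, default_planner, eval_goal

cfg = RunConfig.defaults("timed", pref_mode="explore", zeta=0.0, seed=42, n_agents=5)
res = train(cfg)
print(np.round(res.final_windowed("traj_len_w"), 1))
# [80.  79.6 80.  79.2 79.6]        <- of 80 steps per episode
print(np.round(res.final_windowed("vfe_w"), 4))
# [0.0024 0.0014 0.0014 0.002  0.0024]   <- windowed VFE, nats

env = make_env("timed")
g = eval_goal(res.models[0], env, target_obs=1, rounds=1000,
              planner_cfg=default_planner("timed"), seed=0,
              start_states=[0], include_baseline=False)
print(g.steps.mean(), sorted(g.steps.unique()))
# 3.0 [3]
```

All five agents end up predicting essentially every step of an 80-step
episode (trajectory length ≈ 80) with a variational free energy at its floor
— the world model has become an exact copy of the task. One planning call
(horizon 2, a single refinement iteration, ζ = −1) then reaches satiation
from the initial state in exactly the optimal 3 steps on each of 1000
evaluation rounds: wait while the light is off, wait one more step after it
turns on, then press.

The same workflow is available from the shell:

```bash
feps train --config run.yaml --out runs/demo
feps plan --model runs/demo/model_agent0.json --target-obs 1 --out policy.json
feps eval-predict --model runs/demo/model_agent0.json --env timed --mode super
feps eval-goal --model runs/demo/model_agent0.json --env timed --target-obs 1
```

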