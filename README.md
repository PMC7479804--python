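# assistrl

A reinforcement-learning reasoner that decides, from windowed physiological
signals, whether a cognitively disabled web user currently needs help — and
a synthetic-user simulator so the whole loop can be trained and evaluated
without eye trackers, smartwatches, webcams, or human subjects.

## The problem

Users with cognitive or learning disabilities often cannot operate the very
GUI that offers them content-adaptation tools (symbol annotation, layout
simplification, translation to plain language). The alternative is to infer
need-for-help automatically: collect unobtrusive physiological signals —
heart rate (BPM), heart-rate variability (HRV), blink rate, eye-fixation
duration, gaze position and per-content-type gaze dwell — and learn, per
user, when to trigger the right support tool.

Because affect-detection models generalize poorly across people, the
problem is framed as a Markov decision process solved *per user* by
interaction. Each time step the agent observes a discretized state
$s_t$ built from one 120 s window of aggregated signals and picks an action
$a_t \in \{\mathrm{NOP}, \mathrm{Help}, \mathrm{Ask}\}$: do nothing,
trigger a support tool, or ask via an onscreen dialog. The user's implicit
or explicit feedback determines the reward $r_{t+1}$:

| $a_t$    | no reaction | manual tool trigger | accepts help | rejects help | dialog: wants help | dialog: no help |
|----------|------------:|--------------------:|-------------:|-------------:|-------------------:|----------------:|
| NOP      | 0           | −200                | –            | –            | –                  | –               |
| Help     | +10         | –                   | +10          | −20          | –                  | –               |
| Ask      | −10         | −10 (+10 → Help)    | –            | –            | −10 (+10 → Help)   | −10             |

Missing a user in need (NOP followed by a manual tool trigger) is penalized
hardest; asking always costs a little, but when the answer reveals that help
was needed, retroactive credit of +10 is applied to $(s_t, \mathrm{Help})$.
"–" cells cannot occur and raise an error.

The action-value function $q_\pi(s,a)$ is tabular (default-zero), learned
with Q-learning,

$$Q(s,a) \leftarrow Q(s,a) + \alpha\,[\,r + \gamma \max_{a'} Q(s',a') - Q(s,a)\,],$$

or with double Q-learning (two tables, fair-coin updates) to curb
maximization bias. The behavior policy is a *modified* ε-greedy: at
exploration time, and on value ties at exploitation time, the agent takes
NOP rather than a random action, so tools and dialogs don't pop up at
unsought times for a mostly-calm user.

The synthetic user is a two-state Markov chain over a latent
CONFUSED/CALM affect; confusion shifts the signal emissions (blink bursts,
longer fixations, depressed HRV, slightly raised HR) and drives
probabilistic feedback (an ignored confused user usually triggers a tool
manually; unneeded automatic help is usually rejected).

## Worked example

Library (statsmodels-style model/results objects):

```python
from assistrl import HelpReasonerModel

model = HelpReasonerModel()          # reference user, 120 s windows,
res = model.fit(n_steps=150, seed=1)  # 4 quantile bins, Q-learning
print(res.summary())
print(res.evaluate(n_steps=500).accuracy)
```

Command line:

```console
$ assistrl train --steps 150 --seed 7 --out demo_run
Help Reasoner Training Results
==============================================
algorithm                   q
training steps              150
seed                        7
alpha                       0.1
gamma                       0.9
epsilon (start)             0.1
epsilon (final)             0.01
states visited              85
mean reward                 -31.600
total reward                -4740.0
training accuracy           0.807
==============================================
artifacts written to demo_run

$ assistrl evaluate --qtable demo_run/qtable.json --steps 500 --seed 11
evaluation steps: 500
greedy accuracy:  0.870
```

The mean per-step training reward is strongly negative early on (every
missed confusion episode costs −200) and rises as the table fills in;
training accuracy is the running agreement of the chosen action with the
oracle action (Help when confused, NOP when calm). Greedy evaluation
(exploration off, learning frozen) on a fresh simulated session then gives
the headline accuracy — here 87% for a single run; averaged over 20 seeds
the reference scenario reaches ≈ 91%. `assistrl replay --batches f.jsonl
--qtable q.json` runs a saved policy over a recorded JSON-lines batch file
and prints one action per window.

Runs are configured with a single YAML/JSON file (sections `window`,
`binning`, `learner`, `user_model`, `run`); every parameter of the
synthetic user is exposed there. See `docs/methods.md` for the model
details, defaults, and limitations.

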