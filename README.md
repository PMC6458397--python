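# sociallearn

An associative-learning simulator for studying how social learning phenomena
— stimulus and local enhancement, contextual imitation, transfer of behaviour
from experienced to naive individuals, behaviour-sequence learning, avoidance
learning from warning calls — can emerge from general-purpose learning
mechanisms guided by genetic predispositions, without any dedicated
social-learning machinery.

It is aimed at researchers in animal cognition and behavioural ecology who
want to simulate concrete learning scenarios (which stimuli occur, which
behaviours are possible, what the consequences are, which predispositions the
learner starts with) and compare acquisition curves between social and
individual learning conditions.

## The model

The learner maintains two memories over stimulus *elements*:

* **S–R values** `v(S → B)`: the estimated reward of responding to stimulus
  `S` with behaviour `B` (instrumental learning);
* **stimulus values** `w(S)`: the response-independent estimated reward that
  follows `S` (Pavlovian learning; a learned `w > 0` makes `S` a
  *conditioned reinforcer*).

Each element also has an innate reinforcement value `u(S)` (positive for
primary rewards, negative for innately aversive signals such as warning
calls). After an experience `S → B → S'` both memories are driven towards the
total value of the outcome by error-correcting delta rules with learning
rates α_v and α_w:

    Δv(S → B) = α_v [ u(S') + w(S') − v(S → B) ]
    Δw(S)     = α_w [ u(S') + w(S') − w(S) ]

The `w` update does not depend on the performed behaviour, so it also applies
to witnessed stimulus successions (observational conditioning). Behaviour is
chosen by a softmax over the current stimulus:

    Pr(S → B) = exp(β v(S → B)) / Σ_B' exp(β v(S → B'))

with exploration parameter β (β = 0: uniform choice; large β: near-greedy).
Compound stimuli (several elements at once, e.g. a conspecific plus a novel
food item) follow the classic summation convention: values add across
elements, and an experience with a compound updates every element by the same
amount. Defaults are α_v = α_w = 0.1 and β = 1.

Because learned stimulus values feed back into the S–R update, response
chains assemble by *backward chaining*: an intermediate stimulus that
predicts reward acquires conditioned value, which then reinforces the
earlier response that produces it. Social observations can reshape this
process — by attracting the learner into rewarding situations, and by
endowing intermediate stimuli with value before the learner ever completes
the chain itself.

## Scenarios

Five built-in scenario builders (`sociallearn list-scenarios`), each a
stochastic state machine run for many replicates:

| scenario          | question                                                            |
|-------------------|---------------------------------------------------------------------|
| `social_response` | learning a rewarded response to a social stimulus                    |
| `imitation`       | learning to repeat observed behaviours ([B] → B), and how repertoire size slows it |
| `transfer`        | social exposure bootstrapping a response to a non-social stimulus (with/without an established imitative response) |
| `sequence`        | two-step chain learning (the "food-truck" case): conditioned reinforcement, backward chaining, and its reversal under social learning |
| `avoidance`       | predator avoidance transmitted by innately aversive warning calls; optional heterospecific-call variant |

Custom worlds can be declared in YAML (see `examples/` and
`sociallearn.config`).

## Worked example

Compare social and individual learning of the two-step sequence
`S_x → B1 → S_y → B2 → S_reward`:

```
sociallearn run --scenario sequence --seed 7 --replicates 200 --out demo
```

This writes `demo/sequence/traces.csv` (per-trial means ± standard errors
across replicates, long format) and `demo/sequence/manifest.json` (the fully
resolved parameters and seed, sufficient to re-run the result). Reading the
probability of performing the complete correct sequence:

| learning opportunities | social arm | individual arm |
|---|---|---|
| 0   | 0.010 | 0.010 |
| 50  | 0.953 | 0.208 |
| 100 | 1.000 | 0.497 |
| 300 | 1.000 | 0.919 |

Both arms start at chance (1/10 × 1/10 = 0.01 with ten behaviours per step)
and both eventually master the sequence, but the social arm — attracted to
the situation by conspecifics and able to watch experienced individuals
complete the second step — is far faster. At the final trial the memories
show why: in the social arm `v(S_x→B1) ≈ 21.1`, `v(S_y→B2) ≈ 25.0` and the
intermediate stimulus has acquired strong conditioned value `w(S_y) ≈ 19.9`,
which is what keeps the (never primary-rewarded) first response alive when
no conspecifics are present. Passing `--plots` renders the corresponding
two-panel learning-curve figure.

## Scope

The model deliberately contains no observational S–R learning (responses
change only when performed), no memory for observed behaviour sequences, and
hence no immediate production imitation; no stimulus salience weighting or
continuous stimulus dimensions; and no multi-agent co-learning (experienced
individuals are part of the environment). These are properties of the
modelled learning theory, not implementation shortcuts: the interesting
question is how much social learning emerges *without* them.
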