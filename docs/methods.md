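# Methods

## Learning model

The agent is a genetically guided associative learner. Memory consists of
S–R values `v(element → behaviour)` and stimulus values `w(element)`, both
stored per stimulus *element*; unset entries read as 0. Innate values
`u(element)` are fixed scenario parameters. One experience `S → B → S'`
produces the simultaneous updates

    Δv(S → B) = α_v [ u(S') + w(S') − v(S → B) ]
    Δw(S)     = α_w [ u(S') + w(S') − w(S) ]

where, for compounds, `u`, `v` and `w` of a stimulus are the sums over its
elements, and each element of `S` receives the full common increment (so the
compound value moves by n·Δ for an n-element compound). All quantities on the
right-hand side are evaluated before any update is applied. The error term
always uses the *total* outcome value `u(S') + w(S')` in both rules: the
w-term in the v update is what lets learned stimulus values reinforce earlier
responses (conditioned reinforcement and chaining); dropping it would make
multi-step sequence learning impossible, since early steps never produce
primary reward.

Only the performed behaviour's v entry changes; the w update is
behaviour-independent, and is also applied to witnessed stimulus successions
(`ObservationEvent`s) in which the learner performs no response. Observation
therefore changes what stimuli are *worth*, never directly what to *do* —
the model has no observational S–R learning by design.

Action selection is softmax with exploration parameter β over the v values of
the current compound, computed with max-subtraction for numerical stability.
Defaults α_v = α_w = 0.1 and β = 1 are used everywhere; scenarios that need
pure instrumental learning set α_w = 0.

## Scenario engine

A scenario world is a stochastic state machine. Non-terminal states emit a
compound stimulus from a declared mixture; the transition table maps
(emitted compound, behaviour) to a probability distribution over outcomes
(consequence compound, next state, optional observation events, optional
annotation flags). A trial runs from the start-state distribution to a
terminal state; a guard of 1,000 steps converts non-terminating worlds into
errors. Validation is strict and loud: distributions must sum to 1 (tolerance
1e-9), every referenced name must exist, every emitted compound must have a
transition for every behaviour, and a terminal state must be reachable from
every state.

An outcome may carry no consequence stimulus (`consequence = None`), meaning
the step ends stimulus continuity — the agent's behaviour removes it from the
situation and there is nothing to learn from. No update is applied for such a
step. This is used for escape in the avoidance scenario (see below); such
outcomes must lead to terminal states.

Replicates are averaged trials: each replicate starts from the scenario's
initial memory with an rng derived from `SeedSequence((master_seed,
replicate_index))`, so results are independent of execution order, identical
inputs are bitwise reproducible, and arms share replicate streams (identical
worlds give identical trajectories, which makes paired social-vs-individual
comparisons exact in degenerate cases). Traced quantities are recorded once
per trial *before* the trial runs, plus once after the final trial (row `t`
holds the memory state after `t` completed learning opportunities); reported
response probabilities are the model's softmax probabilities, not empirical
frequencies — the curves are smoother at equal replicate counts — while
per-trial annotation flags (e.g. "escaped", "sequence_completed") provide the
empirical frequencies for cross-checking. Annotation rows are NaN at trial 0,
where no trial has yet run.

## Scenario parameterization

Reward magnitude is `u = 25` for the primary reinforcer in every scenario
(only one scenario's reinforcer magnitude is conventionally fixed; reusing it
everywhere keeps curves comparable). Qualitative predispositions become
concrete defaults: "strong prior response" is `v = 10`, "innately aversive
warning call" is `u = −10`. All are builder arguments.

* **social_response** — one social stimulus; responding `B` yields the
  u = 25 outcome, any other response a neutral one; α_w = 0 (no stimulus-value
  learning is needed). `v(S_social → B)` converges geometrically to 25 with
  rate 1 − α_v; 300 trials × 1000 replicates.
* **imitation** — percepts [B_1]..[B_k] shown equiprobably, matching
  rewarded; `k` is configurable to study the prediction that smaller
  repertoires learn imitation faster (fewer behaviours to try out).
* **transfer** — `S_x` alone 80% of encounters, the social compound 20%;
  responding with the target behaviour is rewarded either way. The repertoire
  has 10 behaviours: exploration cost is what separates the arms, and with
  only two options both arms saturate within a handful of trials (one success
  moves v by 2.5, already Pr ≈ 0.92 at β = 1), leaving no contrast. The
  default horizon of 30 trials is where the primed arm has reached asymptote
  while the naive arm is still acquiring — the region the comparison is
  about. The `with_imitation_prior` variant replaces the conspecific-presence
  element with the percept [B1] of the rewarded behaviour and compares a
  learner that already imitates B1 against a fully naive one.
* **sequence** — the two-step chain `S_x → B1 → S_y → B2 → S_reward`, ten
  behaviours per step (the n^l exploration problem is the point of the
  scenario; with two options it disappears). In the social arm conspecifics
  accompany `S_x` 20% of the time; the learner has the approach prior
  `v(S_social → B1) = 10`; conspecific proximity is itself a primary
  reinforcer, `u(S_social) = 25` — social species find proximity to
  conspecifics rewarding, and without a positive social value the witnessed
  succession `S_y → S_social[B2]` could endow `S_y` with no conditioned
  value at all. While at the second step in company, the learner witnesses an
  experienced individual take and eat the reward with probability
  `P_OBS = 0.5` (the observation frequency is a free parameter; 0.5 matches
  the "half of the time" convention used for companion presence in the
  avoidance scenario). 300 trials reach asymptote in the social arm and
  near-asymptote in the individual arm, so both the speed-up and the
  chaining orders are visible.
* **avoidance** — per encounter the learner has a companion with
  probability 0.5, who calls with probability 0.5; per time step the predator
  leaves on its own with probability 0.2 unless the learner escapes first.
  Ignoring during a calling encounter yields `S_predator → B_ignore →
  S_warning` (u = −10), the key learning event; ignoring otherwise yields
  `S_predator → B_ignore → S_predator`, which spreads the acquired negative
  `w(S_predator)` into the S–R value of ignoring. Escape ends stimulus
  continuity (no consequent stimulus, no update): fleeing into cover leaves
  nothing to learn from, and escape is consequently neither rewarded nor
  punished — avoidance is driven entirely by the negative values, and
  `w(S_predator)` settles around −3.5 instead of being washed out by repeated
  neutral "safety" experiences. The predator leaving is experienced as a
  neutral safe outcome. The no-call arm has no learning signal at all,
  because injury from ignoring a real predator is deliberately not modelled
  (the interesting comparison is the speed of call-based transmission); an
  `ignored_throughout` flag per encounter serves as the injury-risk proxy.
  2000 replicates × 300 trials; the longer horizon is what the
  heterospecific variant needs for `w(S_x)` to converge to `u(S_warning)`
  within 0.5 (the heterospecific call precedes the conspecific call in half
  of the calling encounters, and is always followed by it, so its conditioned
  value inherits the warning value exactly).

## Numerical choices

* Probabilities are validated to 1e-9; softmax normalization is asserted to
  1e-12 in tests.
* The geometric convergence law |v_t − u| = |v_0 − u|(1 − α_v)^t holds to
  float accumulation (~1e-14 over 300 iterations), and is asserted with
  absolute tolerance 1e-10.
* Zero-probability mixture branches are dropped at construction, so a
  degenerate mixture consumes no randomness and a scenario with
  `p_social = 0` is bitwise identical to its individual arm.
* CSV output uses 12 significant digits — lossless for plotting and
  diff-friendly; round-trip is asserted in tests.
* Ties in the softmax argmax need no special handling: sampling is by
  inverse CDF on the exact probability vector.

## What the simulations do and do not show

The worlds are deliberately minimal: stimulus elements are discrete and
noise-free, salience is uniform, encounters are independent trials, and the
experienced animal is a fixed part of the environment rather than a second
learner. Passing tests therefore show that the *learning mechanism* produces
the qualitative phenomena (enhancement, contextual imitation, transfer,
backward chaining and its social reversal, call-based avoidance
transmission) under the stated scenario structures — not that real animals'
parameters are these, nor that the mechanism is the one animals use. Where
figure-level quantities depend on unpublished details (repertoire sizes,
observation frequencies, trial counts), the defaults here are declared
choices, documented above, not claims of numerical identity with any
particular dataset.

## Known limitations

* No observational S–R learning, no sequence memory, no production
  imitation — properties of the theory under study.
* Learning with α_w > 0 in looping worlds can in principle oscillate (values
  feed back into behaviour, which changes the experienced successions); the
  step guard bounds trials, not convergence.
* The trace machinery records scalar quantities only; full per-replicate
  trajectories are available programmatically via
  `collect_replicate_traces`.
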