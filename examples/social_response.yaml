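# Minimal declarative world: learning a rewarded response to a social stimulus.
# Equivalent to the built-in `social_response` scenario.
custom:
  name: social_response
  elements:
    S_social: {u: 0.0, social: true}
    S_reward: {u: 25.0}
    S_no_reward: {u: 0.0}
  behaviours: [B, other]
  parameters: {alpha_v: 0.1, alpha_w: 0.0, beta: 1.0}
  world:
    start: [{state: encounter, p: 1.0}]
    states:
      encounter:
        emissions: [{stimulus: [S_social], p: 1.0}]
        transitions:
          - when: {stimulus: [S_social], behaviour: B}
            outcomes:
              - {p: 1.0, consequence: [S_reward], next: end, annotate: [rewarded]}
          - when: {stimulus: [S_social], behaviour: other}
            outcomes:
              - {p: 1.0, consequence: [S_no_reward], next: end}
      end: {terminal: true}
  trace:
    - {kind: p, stimulus: [S_social], behaviour: B}
    - {kind: v, element: S_social, behaviour: B}
    - {kind: v, element: S_social, behaviour: other}
    - {kind: ann, flag: rewarded, label: "ann:responded"}
  n_replicates: 1000
  n_trials: 300
run:
  seed: 1
  output_dir: runs
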