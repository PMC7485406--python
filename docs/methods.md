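# Model and methods

`pepsim` simulates cued task switching with a Parallel Episodic Processing
(PEP) style model: a small rate-coded network whose only learning mechanism
is an exemplar memory — one stored episode per experienced or instructed
event — read out by similarity-based, recency-weighted, proportional
retrieval.  Switch costs, feature-integration (binding) biases,
cue-repetition benefits, response-repetition asymmetries and task-rule
congruency effects all arise from the same encoding/retrieval cycle; the
only "control" structure is a pair of goal nodes and a staged memory
search.

This note documents the model as this package defines it.  The published
account of this model class describes the architecture conceptually and
prints a named parameter inventory, but the cycle-level update equations
live in supplementary material that is not part of this package's sources.
The equations below are therefore this package's own reconstruction:
faithful to the architectural description and to the printed parameter
names, ranges and values, with every additional fixed constant chosen here
and listed under *Fixed constants*.

## Architecture

Twenty rate-coded nodes in five layers: 4 colour-cue inputs, 8 digit
inputs (1–9 without 5), 4 decision nodes (odd, even, <5, >5), 2 response
nodes (left, right), 2 goal nodes (parity, magnitude).  Digit→decision
links ("3 is odd", "3 is <5") are hardwired pre-existing knowledge; which
colour cues which task and which key expresses which decision exist only
as instructed memory traces.

Each trial: the cue drives its input node for 200 cycles (the cue–target
interval), then the digit comes on (the cue stays visible) for up to 3000
cycles or until a response node crosses threshold; a 500-cycle
response–cue interval of pure decay follows.  One cycle is roughly one
simulated millisecond; RT is counted from target onset.

## Activation dynamics

Activations live in [0, 1] with rest at 0.  A node with positive
deterministic drive `d` moves toward it each cycle,

    a <- a + r * (d * (1 + eps * noise) - a),      eps ~ N(0, 1)

and an undriven node decays multiplicatively (`decay_node`, goals
`decay_goal`).  Noise is multiplicative on the drive (no drive, no noise),
with the layer-specific printed magnitudes.  The rate `r` is
`change_toward_stimulus` for input nodes and
`change_toward_stimulus * central_rate_scale` for decision, response and
goal nodes: central evidence accumulation is slow (a ~600-cycle time
constant) relative to stimulus encoding, which is what spreads simulated
RTs over hundreds of cycles and lets preparation differences survive into
the target period.

Decision drive is `sens * (hardwired_weight * digit_input + retrieval)`
with sensitivity `sens = preparation_base + weight_goal_decision * goal
activation` — the goal gates how strongly a decision takes input.
Response nodes are competing leaky accumulators driven by
`response_gain * search_response_coding * retrieval_share`, with lateral
inhibition `response_competition`; they accumulate only once a decision
has been made.  Goal nodes receive retrieval drive scaled by
`strength_goal` minus lateral inhibition `goal_competition`.

## Episodic store and retrieval

Every episode is a sparse weight row over the 20 nodes plus a decayable
strength.  Instructions are eight two-feature episodes (4 cue–goal, 4
decision–response); each completed trial appends a five-feature episode
(cue, digit, goal, decision, response, with `negative_weights_episode` on
the unchosen response; omissions encode without a response binding).

Similarity is a search-weighted dot product of probe activations with the
episode's weights, over destination-specific probe layers:

* goals are retrieved on the basis of the cue — and of themselves
  (self-retrieval through the episodes that bind them is the carrier of
  goal inertia), with **linear** similarity→activation mapping;
* decisions are retrieved on the basis of cue and target only (no
  decision self-priming loop), **cubic** mapping;
* responses are retrieved by cue, target (at `stimulus_response_weight`,
  so stimulus–response binding is a bias rather than the main route),
  decisions and responses (own term excluded: no self-connections),
  **cubic** mapping, multiplicatively amplified by `1 +
  goal_search_weight * (active bound goal)` so task-consistent memories
  dominate.

The cubic mapping is the classic exemplar-model nonlinearity: episodes
matching on several features dominate partial matches, which keeps
retrieval stimulus-driven even with ~800 stored episodes.  Within each
destination layer the summed positive drive is normalized as
`raw / (1 + total)` — retrieval is proportional, so competing options
share a bounded budget.

Search is staged.  Cue→goal search starts at `strength_cue_search`; once a
goal has been above `threshold_goal` for `goal_confirm_cycles` consecutive
cycles the goal is selected, cue search is damped by
`search_goal_after_selected`, and the target/decision searches come up to
full strength (before that they sit at the same damped base).  A decision
is made when the presented digit's decision on the selected goal's
dimension crosses `decision_threshold`; stimulus search is then scaled by
`search_stimulus_after_decision` and response coding becomes active.
After the trial all searches are damped by `post_trial_damp`.

After each trial, pre-existing episodes are weakened in proportion to
their item-feature similarity to the just-processed event (saturating at
`weaken_saturation` times `loss_episode_connection`; goal bindings alone
do not make an episode a competitor), all strengths decay by
`decay_episode`, and instruction episodes are restored toward their
initial strength by `restore_instruction_episode` (every trial by
default; `restore_after_errors_only` switches to post-error restoration).

## Tunable parameters

The 22 tunables default to the published "Original" values (e.g. change
.034, cue search strength 1.14, episode decay .0022, negative episode
weights −.11) and are validated against their printed a-priori ranges;
the evolutionary fitter mutates exactly these within those ranges
(unbounded ranges get a practical ceiling of 10× max(default, 1)).

## Fixed constants of this reconstruction

| constant | value | role |
|---|---|---|
| `response_threshold` | 0.85 | response emission |
| `decision_threshold` | 0.55 | decision latch |
| `goal_competition` | 1.0 | goal lateral inhibition |
| `response_competition` | 1.5 | response lateral inhibition |
| `hardwired_weight` | 0.55 | digit→decision connection |
| `goal_confirm_cycles` | 20 | debounce of goal selection |
| `goal_search_weight` | 1.0 | goal gating of item retrieval |
| `central_rate_scale` | 0.05 | slow central integration |
| `stimulus_response_weight` | 0.5 | stimulus probe weight at response retrieval |
| `weaken_saturation` | 8.0 | cap on per-trial weakening |
| `response_gain` | 0.45 | retrieval-share → response drive |
| `post_trial_damp` | 0.1 | between-trial search damping |
| `retrieval_refresh` | 8 | cycles between retrieval updates (3 during the race) |

These were calibrated once, jointly, so that the default parameterization
produces the qualitative simulated phenomena with plausible error and
omission rates; they are not part of the fitted space.

## Simulated experiment

The paradigm follows the modeled behavioural study: 800 trials per
simulated participant, trials sampled randomly with replacement, tasks
equiprobable, cues uniform within task, digits uniform; <5/>5 always on
left/right keys and the odd/even assignment counterbalanced across
participants (by participant parity).  Trials are coded into the ten-way
transition taxonomy (cue-RR … alt-AA) from cue/task/stimulus/correct-key
repetition, and into task-rule congruency under the participant's
mapping.  Condition means use correct, non-omitted trials; error rates
exclude omissions; each participant's first trial is excluded from
transition-conditioned statistics; post-error trials are not excluded.
Pooled transition-type means are unweighted means of condition means, and
trial-weighted variants are reported alongside (labelled `_weighted`)
because the two aggregations genuinely differ for derived contrasts.

The goal-inertia ablation replays the same experiment while setting both
goal activations to their arithmetic mean on every cycle of each 500-cycle
response–cue interval.

## What the simulation reproduces, and what it does not

With the default parameterization and 50 simulated participants the
package reproduces, qualitatively: the pooled ordering cue < rep < alt;
cue-RR as the fastest condition; large stimulus-repetition (binding)
benefits within task repetitions; a positive true switch cost
(alt-AA − rep-AA) that the goal-inertia ablation reduces by roughly
two-thirds while binding effects persist; the alt-RA error spike
(≈27% vs ≈29% reported) as the largest error rate; and a strong task-rule
congruency effect in errors.

Known quantitative limitations of this reconstruction (all measured, none
hidden): the overall cycle-time scale sits around 0.4–0.5× the reported
means, and between-condition spread is compressed, so the printed
per-condition cycle times are not matched; the cue-repetition benefit
beyond stimulus repetition is much smaller than reported; the congruency
effect in correct-trial cycle times is near zero (it is robust in
errors); alt-RR rather than alt-AR is the slowest alternation; and the
omission rate is ≈0.5% against the reported 1.7%.  These reflect the
missing published update equations — the reconstruction pins the
architecture and printed parameters but not the exact functional forms.

## Synthetic data and generalization

All inputs are synthesized by the package itself (there is no external
data); the trial generator implements exactly the study design above.  It
does not emulate participant-level heterogeneity (all simulated
participants share one parameter set), fatigue or practice breaks, or any
sequential structure beyond sampling with replacement — so passing tests
certify the model's behaviour under the idealized design, not fits to any
new empirical dataset.

## Numerical choices

Retrieval drive is refreshed every 8 cycles (3 during the response race):
central activations move with a ~600-cycle time constant, so the staleness
is negligible while cutting cost several-fold.  Episodes with strength
below 1e-3 are skipped at retrieval.  Response ties (both accumulators
crossing in one cycle) break toward the more active node, then fixed
layout order.  The fast per-participant driver and the op-level API share
one set of compiled kernels and are covered by an exact equivalence test,
including noise streams.  All randomness flows from integer seeds
(participant *i* uses `base_seed + i`).
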