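# pepsim

An exemplar-memory (Parallel Episodic Processing, PEP) simulator of cued
task switching.

## The problem

In cued task switching, a colour cue tells the participant which of two
tasks to apply to a digit (1–9 without 5): parity (odd/even) or magnitude
(<5/>5), answered with a left or right key.  Responding is slower when the
task switches — the *switch cost* — which is classically attributed to
task-set control.  But switch costs are confounded with *feature
integration*: which combinations of cue, stimulus, decision and response
can repeat from the previous trial differs between task repetitions and
alternations, and repeating (or partially repeating) a just-encoded event
has large effects of its own.

`pepsim` implements a model in which almost everything follows from
episodic memory.  The network stores one memory trace per event —
including the initial task instructions — and responds by
similarity-based, recency-weighted, proportional retrieval of those
traces.  Goal nodes retrieved by the cue sensitize the relevant decision
nodes; a decision retrieves its key.  Switch costs, cue-repetition
benefits, stimulus–response binding effects, response-repetition
asymmetries and task-rule congruency effects all emerge from the same
store, with goal-activation carryover ("goal inertia") as the only
residual task-set component — removable by an ablation that averages the
two goal activations between trials.

The package also includes the feature-pair *points* baseline model (−1
per pair of repeated features, +1 per repeated/non-repeated pair, linear
rescaling onto a reference RT scale) and a steady-state evolutionary
fitter with a reverse-target sensitivity test (can the model be forced to
predict the *opposite* pattern? it cannot; it can only approach null
effects).

See `docs/methods.md` for the full model definition, all parameters and
constants, and a frank account of which published phenomena this
reconstruction reproduces and which it does not.

## Worked example

```python
import pepsim
from pepsim.experiment import run_experiment, summarize, compute_effects

params = pepsim.PEPParameters()          # published "Original" values
df = run_experiment(params, n_participants=10, base_seed=500, n_trials=800)
summary = summarize(df)
print(summary.table.round(1))
print(compute_effects(summary, df).round(1))
```

prints (10 participants; cycle times in cycles, errors in %):

```
  condition  mean_rt  error_pct     n
0    cue-RR    294.5       21.0   248
1    cue-AR    352.2       16.3   763
2    cue-AA    350.9       18.6  1043
3    rep-RR    301.7       15.3   242
4    rep-AR    354.4       15.4   727
5    rep-AA    351.2       16.2   987
6    alt-RR    417.8        9.1   264
7    alt-RA    411.4       23.8   223
8    alt-AR    370.6       16.8  1717
9    alt-AA    362.8       15.5  1743
```

Reading it: the complete cue repetition (cue-RR) is fastest; within task
repetitions, repeating the stimulus (RR vs AR) buys ~55 cycles; all task
alternations are slower (a ~56-cycle pooled switch cost), and repeating
the stimulus with a changed response (alt-RA) produces the error spike
(~24%) — partial repetitions hurt.  `compute_effects` reports the derived
contrasts (true switch cost alt-AA − rep-AA, cue-repetition benefit,
response-repetition benefits, congruency effect and its interaction with
switching), each in an unweighted-condition-mean and a trial-weighted
variant.

Command line, for the same pipeline plus the ablation, the points
baseline, fitting and condition-coding of external CSVs:

```bash
pepsim simulate --n-participants 50 --seed 1 --out runs/default
pepsim simulate --n-participants 50 --seed 1 --ablate-goal-inertia --out runs/ablated
pepsim altmann --out runs/altmann.csv
pepsim sensitivity --out runs/sensitivity     # reverse-target fit
pepsim code --trials-csv mydata.csv --out coded.csv
```

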