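# relearnn

Reward-driven learning of perceptual grouping in recurrent neural
networks with excitatory, inhibitory and modulatory connections.

## The problem

When monkeys learn to detect a string of collinear bars or to trace a
curve to its endpoint, neurons in early visual cortex start to label the
grouped image elements with enhanced activity — but only after a delay,
carried by horizontal and feedback connections.  The only feedback the
animal receives is a reward for correct behavior.  How can a reward
signal, broadcast globally, teach a *recurrent* circuit — feedforward,
lateral and feedback connections at once — to perform this incremental
grouping?

`relearnn` implements a biologically inspired answer for networks of
shunting units

    dp/dt = -αp + (β - p) I_ex (1 + γ I_mod) - (ζ + p) I_inh,
    r = g(p) = a + p  (p ≥ 0),   a e^{p/a}  (p < 0),

whose motor-layer potentials at the network's fixed point estimate
action values Q_a.  An action is drawn from a softmax over the motor
potentials.  Credit assignment runs through an **accessory network**:
the winning unit injects activity into a linear circuit reciprocal to
the regular network linearized at its fixed point, so each accessory
activity Δp_l converges to the influence of unit *l* on the chosen
action's value (Δp = -L⁻¹J with L the transposed Jacobian and J the
winner injection).  A globally released reward-prediction error
δ = ϱ - Q_a then gates a three-factor Hebbian update

    ΔW_kl = η · δ · Δp_l · f_l(p_l) · r_k,

with a class-specific postsynaptic factor f (excitatory, inhibitory or
modulatory).  This update is exact gradient descent on δ², verified in
the test suite against central finite differences over every plastic
weight of random mixed networks.

Two testbeds from the neurophysiology of perceptual organization are
included, built on one architecture family (input maps → linking layer
with disynaptic inhibition and lateral/feedback modulation →
association layer → motor layer):

- **Contour linking** — saccade to the aperture (of two 9×9 bar fields)
  that contains 1–9 collinear bars; after learning, linking-layer
  activity increases with contour length and the effect vanishes when
  the modulatory connections are silenced, as in area V1 recordings.
- **Curve tracing** — saccade to the green marker on the curve cued by
  a red dot; analysis utilities measure the incremental-grouping
  signatures of the trained network: the spread of enhanced activity
  from the cue over the connected curve (never across gaps) and the
  latency of the enhancement as a function of distance from the cue.
  See `docs/methods.md` for what the desk-scale training runs do and
  do not establish on this task.

## Worked example

Run the contour-linking study — contrast-ramp shaping, then 15,000
trials of the full task with contour lengths 1/3/5/7/9 interleaved —
and print the greedy accuracy per contour length:

```python
from relearnn import presets

result = presets.train_contour_study(seed=3)
acc = presets.contour_accuracy_by_length(result.log)
print(result.trials_used)
print({L: round(a, 3) for L, a in sorted(acc.items())})
```

This prints

```
16000
{1: 0.489, 3: 0.988, 5: 0.99, 7: 0.991, 9: 0.993}
```

a single-element "contour" is indistinguishable from the distractor
field (chance is 0.5), while genuine collinear contours are detected
nearly perfectly, with accuracy increasing with contour length.  After
this training, the linking-layer potential of the unit with the center
element in its receptive field grows with contour length
(`relearnn.analysis.contour_length_tuning`), and zeroing the lateral and
feedback modulatory weights (`relearnn.ablate(..., "both")`) abolishes
the length tuning while the visual drive remains — the model analogue of
the anesthesia experiment.  The CLI wraps the same machinery
(`relearnn train --task contour --seed 3 --out run/`, then
`relearnn evaluate`, `relearnn ablate`, `relearnn record`).

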