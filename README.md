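# paingate

A seeded, testable simulator of the spinal **gate control of pain** circuit,
for computational neuroscientists and pain researchers who want to study how
two generic neuronal regulation mechanisms — NMDA-style synaptic plasticity
and intrinsic (firing-threshold) plasticity — are enough to produce both the
normal gating of pain by touch and a family of pathological pain conditions
(phantom limb pain, dysesthesia in demyelinating syndromes, breakthrough,
wind-up and wind-down pain).

## The model

Two rate-code neurons form the gate: a substantia gelatinosa (SG)
interneuron that inhibits the central transmission (CT) neuron whose output
O₂ is the pain signal. Both receive the sensory afferent I₁ and the
nociceptive afferent I₂ through strictly excitatory plastic synapses
w₁…w₄ (probabilities throughout):

```
Net₁ = w₁I₁ + w₃I₂           O₁ = σ(Net₁; s₁)
Net₂ = w₂I₁ + w₄I₂ − O₁      O₂ = σ(Net₂; s₂)
σ(net; s) = 1 / (1 + e^(−k(net + 0.5 − 2s))),   k = 50
```

Each neuron's firing threshold is t = 2s − 0.5. After every presentation,
synaptic weights follow the presynaptic rule — the conditional probability
of a postsynaptic spike given a presynaptic spike, w = n(o∧i)/n(i),
estimated from sampled binary spikes — and each shift relaxes toward the
neuron's output, s ← (υO + s)/(υ + 1). The self-reinforcing weight rule and
the homeostatic threshold rule counterbalance each other; which setpoint
they reach, and hence which pain condition the gate expresses, is decided
by the stimulation regime. See `docs/methods.md` for the full account.

## Worked example

Train the gate on the standard regime (sensory 0.6, nociceptive 0.3, all
four presence/absence combinations per iteration):

```
$ paingate run --scenario standard --iterations 300 --seed 1
scenario: standard  seed: 1  iterations: 300
setpoint: w1=0.995  w2=0.000  w3=0.493  w4=0.507  s1=0.512  s2=0.274  t1=0.523  t2=0.049
final truth table (probe epoch):
     I1      I2    net1      o1    net2      o2
 0.0000  0.0000  0.0000  0.0000 -0.0000  0.0803
 0.6000  0.0000  0.5912  0.9683 -0.9683  0.0000
 0.0000  0.3000  0.0976  0.0000  0.2024  0.9995
 0.6000  0.3000  0.6888  0.9998 -0.7974  0.0000
condition: normal
```

The weights have converged to (1, 0, 0.5, 0.5) and the shifts to
(0.51, 0.27): the gate's healthy operating point. The truth table reads row
by row: no input → resting CT output 0.08 (no pain); touch alone →
silence; nociception alone → O₂ ≈ 1.0, pain relayed; touch *and*
nociception → the SG neuron fires (o1 ≈ 1) and its inhibition gates the
pain (O₂ ≈ 0) — rubbing the spot where it hurts works.

The same circuit, trained through an amputation protocol, learns to hurt
with no input at all:

```
$ paingate run --scenario phantom --seed 3
...
     I1      I2    net1      o1    net2      o2
 0.0000  0.0000  0.0000  0.0015 -0.0015  0.9465
...
condition: phantom
```

The CT threshold has gone negative (t2 = −0.12 here): the neuron fires
spontaneously — phantom pain as a peripheral setpoint of the gate rather
than a top-down phenomenon.

Other entry points: `paingate sweep` classifies the trained condition across
the whole (sensory, nociceptive) intensity plane; `paingate report`
summarises a saved trajectory CSV. Everything is also available as a
library (`paingate.run_scenario`, `paingate.multi_init_study`,
`paingate.phase_sweep`, ...), and scenarios round-trip through YAML.

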