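# Methods

## Model

The package simulates a two-neuron rate-code circuit implementing the spinal
gate control of pain. A substantia gelatinosa (SG) interneuron and a central
transmission (CT) neuron each receive the sensory (mechanoreceptor) afferent
I₁ and the nociceptive afferent I₂ through plastic, strictly excitatory
synapses:

```
w1: I1 -> SG    w2: I1 -> CT
w3: I2 -> SG    w4: I2 -> CT
```

The SG neuron inhibits the CT neuron through a fixed synapse of magnitude 1.
All signals are firing probabilities in [0, 1]. The forward pass is

```
Net1 = w1·I1 + w3·I2            O1 = σ(Net1; s1)
Net2 = w2·I1 + w4·I2 − O1       O2 = σ(Net2; s2)
```

with the shifted sigmoid `σ(net; s) = 1 / (1 + exp(−k(net + 0.5 − 2s)))`.
The shift `s ∈ [0, 1]` positions the curve: the firing threshold — the net
input at which the neuron fires with probability one half — is `t = 2s − 0.5`,
so thresholds range over [−0.5, 1.5]. The exponent's parenthesisation is the
unique reading consistent with the two limit cases (s = 0: O(net=0) ≈ 1;
s = 1: O(net=1) ≈ 0) and with the threshold law. O₂ is the pain signal
relayed toward the brain.

Two adaptation rules act after every presentation of an input pair:

- **Synaptic (presynaptic-rule) plasticity.** Each weight is the conditional
  probability of a postsynaptic spike given a presynaptic spike,
  `w = n(o ∧ i) / n(i)`, estimated from fictitious binary spikes sampled
  from the pre- and postsynaptic rates. The rule is self-reinforcing and
  alone drives weights toward saturation.
- **Intrinsic plasticity.** The shift relaxes toward the neuron's recent
  output, `s ← (υ·O + s) / (υ + 1)` — a convex combination, so `s` stays in
  [0, 1] and approaches a constant output geometrically with ratio
  1/(1 + υ). A chronically active neuron thereby raises its threshold, a
  silent one lowers it; this counterbalances the weight rule, and only the
  two rules together give reproducible setpoints.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` (slope_factor) | 50 | sigmoid steepness; near-step transition (dimensionless) |
| `υ` (upsilon) | 0.05 | intrinsic-plasticity rate; re-adapts within a few tens of iterations without hard oscillation against the near-step sigmoid |
| `decay` | 0.99 | forgetting factor of the spike tallies; ~100-presentation memory so scenario regime changes re-converge. `decay = 1` is the literal lifetime count and is what stationary (standard-training) analyses use |
| `inhibition` | `"rate"` | the SG→CT term in the plasticity step: the SG output rate O₁ (expected-value form, matching the truth-table arithmetic). A `"spike"` variant gates CT with the sampled SG bit instead; see Limitations |
| pain cut | 0.5 | CT rate above which a truth-table response counts as "pain present" (the sigmoid midpoint) |

One seeded generator drives the whole run; per presentation the draws are
consumed in fixed order (input bits i₁, i₂; SG output bit; CT output bit),
so a (scenario, seed, config) triple reproduces a bit-identical trajectory.
Initial weights and shifts are Uniform(0, 1) unless given explicitly.

## Stimulation protocols

An *epoch* is the set of input pairs presented within one iteration; the
standard epoch is the four presence/absence combinations with sensory 0.6
and nociceptive 0.3, reflecting the higher firing rate of myelinated
mechanoreceptor afferents. Verbal intensities map to representative
probabilities (very intense 0.9, intense 0.7, medium 0.5, weak 0.3, very
weak 0.1) inside fixed intervals. Scenarios are phase sequences; every one
starts with 50 standard iterations so pathology develops out of a normally
trained gate:

- **phantom**: 50 null-input iterations (amputation), then 50 iterations of
  very-weak (0.1, 0.1) combinations (neuroma firing); plasticity on
  throughout. All four weak combinations are presented — the protocol's
  "very subtle inputs" reading adopted here.
- **demyelinating**: sensory weakened to 0.3 for 50 iterations, then
  nociceptive raised to 0.5 for 50 more.
- **breakthrough**: intense nociception (0.7, the intense-interval midpoint;
  overridable) on top of normal touch for 100 iterations.
- **wind_down**: sole nociceptive stimulus of 1.0 for 50 iterations, then a
  frozen-plasticity test on the standard combinations.
- **wind_up**: sole very-weak (0.1) sensory stimulus for 50 iterations, then
  the frozen test.
- **dual_intense**: sole (0.9, 0.9) stimulus for 50 iterations, then a
  frozen test on the very-intense combinations.

In sole-stimulus phases the epoch degenerates to one pair per iteration;
the iteration counter semantics are unchanged.

## Analyses and numerical choices

- **Trajectories** log all six parameters and the CT response to a fixed
  probe epoch once per iteration; the probe is evaluated purely and never
  feeds plasticity.
- **Setpoints** are trailing-window means (default 100 iterations; the
  standard-convergence analyses use 500 of 5000) rather than final instants,
  because the shift updates cycle through the epoch's patterns and the
  weight estimator carries Bernoulli counting noise.
- **Convergence** is declared when every parameter's trailing-window range
  falls below a tolerance. The weight estimator's noise floor after n
  presentations is ≈ 0.5·√(events)/n; at 5000 iterations this is ~1.3e-3
  over a 100-iteration window, so convergence of stochastic runs is asserted
  at tolerance 0.01, not at the 1e-3 that a deterministic trace would meet.
- **Condition labels** are rule-based on the final four-row truth table:
  wind_down if every response is below the pain cut; phantom/wind_up if the
  null input is painful (phantom when the probe stimuli are themselves at
  most very weak, ≤ 0.2); dysesthesia if the sensory-only input is painful;
  normal if exactly the nociceptive-only input is painful; otherwise mixed.
- The **phase sweep** trains a fresh circuit per (sensory, nociceptive)
  intensity pair on the combination epoch at those intensities and labels
  the setpoint; it reproduces the qualitative chart (normal below the
  input-intensity diagonal, dysesthesia above, wind-up/phantom at the weak
  edges).
- Degenerate inputs need no special casing: negative net inputs (strong
  inhibition) pass through the sigmoid; a synapse whose afferent never
  spikes keeps its initial weight (the conditional probability is undefined,
  never divided by zero); sole-stimulus epochs simply shorten the iteration.

## What the simulations do and do not show

The simulator generates all of its own inputs; there is no external data.
Runs reproduce: the standard truth table (pain only for nociceptive-only
input, gated by concurrent touch); convergence of five random
initialisations to the common setpoint w = (1, 0, 0.5, 0.5),
s = (0.5, 0.27) — equivalently thresholds ≈ (0.51, 0.04); its resting CT
output ≈ 0.1; non-convergence under either plasticity rule alone; phantom
setpoints emitting pain at null input with CT threshold ≈ −0.05;
demyelination dysesthesia; and wind-up (pain at null input after repetitive
weak touch). Note the threshold law gives t₂ = 0.04 at s₂ = 0.27, while 0.02
corresponds to s₂ = 0.26; both lie within the run-to-run spread.

Two outcomes this class of gate model is often credited with do **not**
emerge at these defaults, and the package reports them as found rather than
specialising parameters per scenario:

- **Wind-down.** Under a sustained sole nociceptive input the SG neuron
  self-ignites: for a self-driven loop the net input tracks the output O
  while the threshold 2s − 0.5 crosses it at O = 0.5, so the SG settles at
  half-maximal firing. Its steady rate inhibition then silences the CT
  neuron, whose threshold decays below zero — hyperexcitability rather than
  the described global hyporesponsiveness. The hyporesponsive outcome does
  appear for υ ≳ 0.2, and robustly under the `"spike"` inhibition variant
  (where CT fires whenever the sampled SG spike is absent and its threshold
  climbs); but the spike variant in turn abolishes the phantom and wind-up
  setpoints, so the rate form — which matches the truth-table arithmetic and
  the phantom threshold −0.05 — remains the default.
- **Dual-intense wind-down.** With both inputs at 0.9 the SG drive
  0.9·(w1 + w3) approaches 1.8, above the maximum attainable threshold 1.5,
  so the SG can never wind down; the CT stays gated at the both-intense pair
  while its own threshold collapses, and the frozen test shows the
  complementary pattern (pain for null and single inputs, none for the
  both-intense pair) for every seed and under both inhibition modes. Under
  the model equations as implemented this outcome is structural, not a
  matter of seeds or rates.

The model is phenomenological: one SG/CT pair, no descending modulation, no
temporal spike structure, no inhibitory plasticity, and an activation with
σ(0) > 0 (a variant with f(0) = 0 would silence the resting output entirely
but is not defined by the model and is not implemented). Passing simulations
therefore demonstrate properties of this idealised circuit, not quantitative
predictions for real dorsal-horn recordings.
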