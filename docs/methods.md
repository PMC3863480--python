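# Methods

## Model

The simulated net is a feedforward lattice: `m` input neurons at the
bottom, `m` parallel cortical columns of `n` concatenated block
segments, and `n` feature classifier (output) neurons reading the
layers from the side. A block segment is the elementary microcircuit:
its signal path bifurcates into a direct path and a path through one
delay neuron, recombining at a junction. Signal transit through a
segment takes 1 integer clock step on the direct path and 2 on the
delay path. The paper-level physical anchor is 1 ms per clock step; the
simulator itself is unit-free.

A binary `m × n` input pattern is presented row-serialized: row `t` of
the image fires its active input channels at clock step `t`. Each input
event injects one signal into its column; the signal's arrival time at
layer `l` is its injection time plus the cumulative transit of segments
`1..l` (the input layer, layer 0, is permanently clamped direct).
Output neuron `k` spikes at the first clock step at which the number of
distinct columns holding a signal at layer `k` exceeds its threshold;
thresholds default to `m − 1`, so the full planar wave front is
required. One spike per output per presentation; network state is
cleared between presentations. Where a pattern places several events in
one column each event is an independent signal, but coincidence counts
distinct columns, so duplicated columns never double-vote.

Path selection is stochastic during learning. Per presentation, every
segment draws one uniform number and routes via the delay path iff the
draw is ≥ P_direct, with

    P_direct = e^(w_direct/T) / (e^(w_direct/T) + e^(w_delay/T))

evaluated with the layer's own Boltzmann temperature T. This is
computed as the logistic sigmoid of `(w_direct − w_delay)/T`, which is
the same expression without overflow at small T. Only `w_direct` is
stored; `w_delay = 1 − w_direct` is derived, which makes the
complementarity invariant exact by construction.

## Learning rule

If at least one output spikes in a presentation, the **lowest-index**
spiking layer learns (see "Design choices" for why); for every segment
of that layer the sampled path is reinforced:

    w_sel   ← w_sel + (1 − w_sel)·α
    w_desel ← w_desel − w_desel·α

The two increments cancel for a complementary pair, so w_direct +
w_delay = 1 is preserved exactly; `(1, 0)` is the only stationary pair,
and iterating the rule from any interior state converges geometrically
to it (distance shrinks by the factor `1 − α` per event). The spiking
layer's temperature is then lowered by δT, floored at T_min. Training
stops when every trainable weight is within `convergence_tol` of 0 or 1
or when `max_presentations` is reached; the latter is a reported
outcome with diagnostics (per-layer temperatures, a histogram of weight
distances), never an exception.

The rule is unsupervised: a spike reinforces whatever routing produced
it, regardless of which pattern was shown. Correct class mapping is an
emergent property; the test suite measures it by checking every
converged configuration against the exhaustive feasibility oracle.

## Parameters

| parameter          | default | meaning                                            |
|--------------------|---------|----------------------------------------------------|
| `T_max`            | 1.0     | starting Boltzmann temperature of every layer      |
| `T_min`            | 0.05    | annealing floor; gating is near-deterministic here |
| `delta_T`          | 0.005   | temperature decrement per learning event           |
| `alpha`            | 0.01    | learning slope; fraction of remaining distance     |
| `convergence_tol`  | 1e-3    | binarization tolerance                             |
| `max_presentations`| 100 000 | presentation cap                                   |
| `threshold_offset` | 0       | non-positive shift of all output thresholds        |

Temperatures and α are dimensionless; times are clock steps. The
annealing floor is reached after `ceil((T_max − T_min)/δT) = 190`
learning events per layer, well before the ~600 events a layer needs to
binarize within 1e-3 at α = 0.01 — so a layer's gating is effectively
frozen by its weights, not by the temperature floor. These defaults are
a desk-scale regime: with a very low α the same process requires
pattern sets to be applied several hundred thousand times; at α = 0.01
the minimal 2×2 circuit converges in roughly 1.5–2k presentations and
the 3×3 net in under ~20k, which keeps full 20-seed sweeps in the test
suite at seconds of runtime. Lowering thresholds
(`threshold_offset < 0`) accelerates coincidence detection and buys
robustness to lost delay lines at the cost of selectivity margin.

## Analytic configuration and oracle

For single-onset-per-column ("bar convention") pattern sets the correct
routing has a closed form. Writing `s_i(k)` for the onset of column `i`
in class `k`, the signal of column `i` reaches layer `k` at
`s_i(k) + k + c_i(k)` where `c_i(k)` is its cumulative delay count over
layers `1..k`. A planar front at layer `k` therefore requires
`c_i(k) = C_k − s_i(k)` for a uniform shift `C_k ≥ max_i s_i(k)`.
Consecutive classes must differ by 0 or 1 delays per column — otherwise
no placement exists and the offending (column, class) is reported. The
builder uses the smallest feasible shift (fewest delays, placed as
early as possible — the canonical form), and verifies the result by
propagation before returning it. For bar sets generated by the
staircase rasterization the per-layer placement is in fact forced, so
canonicalization never has to break a tie.

The independent oracle is exhaustive: all `2^(m(n−1))` admissible
binary configurations (bounded at 2^12) are propagated against every
pattern, keeping those for which pattern `k` fires exactly output `k`.
The analytic configuration is asserted to be a member wherever
enumeration is feasible, and every converged learned configuration is
checked for membership. No closed form is attempted for sinusoids;
they are handled by the brute-force route only.

A structural consequence worth noting: the all-direct configuration is
*not* a harmless identity. A zero-skew (horizontal-bar) input then
stays a planar front at every layer, so all outputs fire — the decoder
reports this as ambiguous rather than resolving it to any class.

## Synthetic stimuli

The generator produces the study conditions themselves, not a
surrogate: bars are staircase rasterizations `t_i = round(i·k/(m−1))`
(half-up rounding — the rule fixes the horizontal and 45° endpoints and
interpolates monotonically), sinusoids are
`round(c + a·sin(2π·f·t/n + φ))` clipped to the channel range with one
active channel per step, and the two-electrode V/D pair is the
paired-pulse MEA protocol (V: both electrodes at t₀; D: electrode 2 at
t₀, electrode 1 at t₁). What the generator does **not** emulate is
everything a cultured network adds on top: stimulation artifacts,
unreliable synapses, background self-spiking, electrode coverage gaps.
Passing tests therefore demonstrate the computational model's internal
consistency and its equivalence to the analytic transform — they do not
predict that an in vitro preparation will reach the same fixed point.
The perturbation module (uniform integer timing jitter, i.i.d. event
dropout, whole-column ablation) probes robustness within the model, not
biophysical noise.

## Design choices

- **Transit times.** Only the delay neuron's extra step is fixed by the
  model (1 ms); the direct path's base cost is a convention. We charge
  1 step per segment on the direct path, 2 on the delay path. Any
  uniform base offset shifts all spike times equally and leaves the
  coincidence structure unchanged.
- **Learning scope.** A spike of output `k` updates layer `k` only.
  Lower layers are treated as already conditioned, higher layers are
  untouched; combined with the lowest-index tie rule this produces the
  bottom-up sequential settling the model calls for (each layer has its
  own temperature, and a settled layer `k` makes pattern `k` always
  fire output `k`, which then shields higher layers from conflicting
  reinforcement by lower-class patterns).
- **Tie rule.** If several outputs reach coincidence in one
  presentation (common mid-training: once layer `k` is planar, a
  uniformly routed next layer is planar too), all spikes are recorded
  in the trace, but only the lowest-index layer learns.
- **Annealing trigger.** The temperature is lowered on any
  learning-triggering spike, not only "correct" ones — the rule has no
  notion of correctness to condition on.
- **RNG.** One named generator (numpy PCG64) owned by the network,
  seeded from the config; serialization round-trips its state exactly,
  so a run saved mid-training and resumed is bit-identical to an
  uninterrupted one. Weights are serialized as hex-encoded IEEE-754
  bit patterns for the same reason.
- **α = 0** is accepted (null learning rate) so that no-learning
  control runs are expressible; it trivially never converges and is
  reported as such at the cap.
- **Degenerate inputs.** Empty patterns propagate to empty traces and
  decode to `None`; a silent or multi-output presentation is a
  first-class outcome category in every report, never coerced to a
  class.

## Problem sizes

The package's standard experiments are the 2×2 circuit on the V/D pair
(20 seeds), the 3×3 net on three bar classes (20 seeds, also the
sequential-settling measurement), and the deterministic 9×9 analytic
configuration on the nine-bar set. Exhaustive enumeration is used up
to 12 free bits (2×2: 4 configurations; 3×3: 64). These sizes make
every sweep exact or fully replicable in seconds while exercising all
mechanisms; nothing in the implementation is specialized to them, and
`m`, `n` scale freely.

## Known limitations

- No continuous-time membrane dynamics, subthreshold integration, or
  dendritic delays — the clock is integer and the neurons are
  coincidence counters, as in the source model.
- The unsupervised rule can transiently reinforce off-target routing in
  higher layers before lower layers settle; with the default annealing
  schedule this resolves, but pathological schedules (δT far too large
  relative to α) can freeze a layer early. The non-convergence report
  exists to make that visible.
- The analytic builder requires single-onset-per-column patterns;
  sinusoids with revisited channels are verified only by enumeration,
  within its size bound.
- MEA export carries timing only; pulse amplitude, width and electrode
  geometry are outside the model.
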