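# columnhough

A cycle-accurate simulator of a self-structuring neuronal net in which
repetitively applied spatiotemporal pattern sets induce the formation of
cortical columns and microcircuits that decode distinct patterns — the
computational counterpart of the classic orientation-selectivity
experiments, and the design tool for their in vitro replay on
microelectrode arrays (MEAs).

It is written for computational neuroscientists and for experimentalists
planning pattern-induced learning experiments with cultured neuron
ensembles: the same package that simulates the learning also exports the
stimulation timelines ("played like a piano") and provides the
brute-force oracle needed to interpret a minimal in vitro circuit.

## The model

The net has `m` input neurons, `m × n` delay neurons and `n` output
(feature classifier) neurons. Each input neuron drives one *cortical
column*: a chain of `n` block segments whose signal path bifurcates into
a **direct path** (1 clock step) and a **delay path** (2 clock steps —
every delay neuron adds exactly 1 ms at the default 1 ms/step scale).
The branch taken is governed by the antagonistic weight pair
(w_direct, w_delay), w_direct + w_delay = 1, drawn per presentation from
a Boltzmann path-selection probability with per-layer temperature T:

    P_direct = e^(w_direct/T) / (e^(w_direct/T) + e^(w_delay/T)),   P_delay = 1 − P_direct

Output neuron `k` reads layer `k` and spikes when more than
`threshold_k` (default `m − 1`, i.e. all) columns hold a signal there at
the same clock step — a *planar wave front*. When an output spikes, the
sampled routing of its layer is reinforced,

    w_sel ← w_sel + (1 − w_sel)·α,      w_desel ← w_desel − w_desel·α,

and that layer's temperature is lowered by δT (floored at T_min).
Learning is unsupervised and finishes when every weight has binarized to
0 or 1; the frozen gates then act as deterministic switches. The learned
routing is equivalent to a Hough-style coordinate transform: each bar
slope (or sinusoid frequency) maps to one point of an ordered feature
space, read out as a **time-and-place code** (which output fired, and
when, relative to the first input event). For bar sets the configuration
is also analytically derivable — the cumulative delay count of each
column must compensate its input-onset skew — and the package verifies
the learned solutions against both that closed form and an exhaustive
enumeration of all feasible binary configurations on small nets.

## Worked example: the minimal circuit

The smallest interesting net has two input neurons, four delay neurons
and two output neurons, trained on the two MEA sequences: V (both
electrodes pulse at t₀) and D (electrode 2 at t₀, electrode 1 at t₁).

```python
from columnhough import (NetworkConfig, build_network, fixture_fig5, train,
                         truth_table, convergence_report, get_binary_matrix)

cfg = NetworkConfig(alpha=0.01, seed=42)
net = build_network(2, 2, cfg)          # 2 inputs, 4 delay neurons, 2 outputs
result = train(net, fixture_fig5())
print("converged:", result.converged,
      "after", result.presentations_used, "presentations")
print("learned gating (1=direct, 0=delay):")
print(get_binary_matrix(result.network))
print("truth table holds:", truth_table(result.network)["matches_expected"])
report = convergence_report(result)
print("truth table stable from presentation", report["truth_table_stable_iteration"])
```

prints

```
converged: True after 1600 presentations
learned gating (1=direct, 0=delay):
[[1 1]
 [1 0]]
truth table holds: True
truth table stable from presentation 6
```

The learned matrix is exactly the configuration the circuit needs: the
leading column's layer-1 segment routes through its delay neuron
(bit 0), every other segment stays direct, so V fires output 1 of the
circuit (index 0) and D fires output 2 (index 1) — the minimal-circuit
truth table. The stability iteration reports how early the rounded
gating already implied the final truth table, long before the weights
finished binarizing.

The same workflow scales to the nine-bar 9×9 set from the shell:

```bash
columnhough generate --kind bars --m 9 --n 9 --out patterns.json
columnhough oracle --m 9 --n 9 --out config.json
columnhough verify --net config.json --patterns patterns.json
columnhough export-protocol --gap 10 --reps 100 --clock-ms 1 --out protocol
```

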