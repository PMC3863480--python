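"""End-to-end assessment: discrimination, the minimal-circuit truth table,
and convergence diagnostics.

After training, the net is probed with its pattern classes and the
time-and-place read-out is tallied into a confusion matrix.  Silent and
ambiguous (multi-output) presentations are first-class outcome
categories, never coerced to a class.  For the minimal 2-input /
4-delay-neuron / 2-output circuit the behavioral contract is a truth
table: simultaneous input on both channels fires output 0, the
staggered (diagonal) sequence fires output 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netmodel import Network, get_binary_matrix
from .stimuli import PatternSet, fixture_fig5
from .dynamics import GatingSample, propagate, decode, AmbiguousDecodeError, sample_gating
from .plasticity import TrainingResult, is_converged

__all__ = [
    "DiscriminationReport",
    "discriminate",
    "truth_table",
    "convergence_report",
]

NO_SPIKE = -1  # confusion column indices beyond the n decoded classes
AMBIGUOUS = -2


@dataclass(frozen=True)
class DiscriminationReport:
    """Confusion tally of a discrimination run.

    ``confusion`` has shape ``(n, n + 2)``: row = true class, columns
    ``0..n-1`` = decoded class, column ``n`` = no spike, column ``n+1`` =
    ambiguous (several outputs fired).  Row sums equal the presentations
    per class.  ``accuracy`` is the diagonal fraction;
    ``per_pattern_spike_times[k]`` lists the relative spike times of the
    correctly decoded presentations of class ``k``.
    """

    confusion: np.ndarray
    accuracy: float
    per_pattern_spike_times: dict[int, list[int]]
    labels: tuple[float, ...]

    @property
    def n(self) -> int:
        return self.confusion.shape[0]


def discriminate(
    net: Network,
    patterns: PatternSet,
    repetitions: int = 1,
    rng: np.random.Generator | None = None,
) -> DiscriminationReport:
    """Present every pattern ``repetitions`` times and tally the read-out.

    A fully binarized net is evaluated with its deterministic gating; a
    net still carrying fractional weights is sampled stochastically
    (``rng`` defaults to the network's own generator).
    """
    if patterns.width != net.m:
        raise ValueError(
            f"pattern width {patterns.width} does not match network m={net.m}"
        )
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    n = net.n
    if len(patterns) != n:
        raise ValueError(f"pattern set has {len(patterns)} classes, network has {n}")
    deterministic = is_converged(net, 0.5 - 1e-12) or is_converged(net)
    fixed_gating = GatingSample(get_binary_matrix(net)) if deterministic else None

    confusion = np.zeros((n, n + 2), dtype=int)
    spike_times: dict[int, list[int]] = {k: [] for k in range(n)}
    for k, pattern in enumerate(patterns):
        for _ in range(repetitions):
            gating = fixed_gating if fixed_gating is not None else sample_gating(net, rng)
            trace = propagate(net, gating, pattern)
            try:
                decoded = decode(trace)
            except AmbiguousDecodeError:
                confusion[k, n + 1] += 1
                continue
            if decoded is None:
                confusion[k, n] += 1
            else:
                confusion[k, decoded[0]] += 1
                if decoded[0] == k:
                    spike_times[k].append(decoded[1])
    accuracy = float(np.trace(confusion[:, :n])) / float(confusion.sum())
    return DiscriminationReport(
        confusion=confusion,
        accuracy=accuracy,
        per_pattern_spike_times=spike_times,
        labels=tuple(patterns.labels),
    )


def truth_table(net: Network, patterns: PatternSet | None = None) -> dict:
    """Evaluate the minimal 2x2 circuit against its behavioral contract.

    Presents the vertical (V: both channels at t0) and diagonal (D:
    channel 2 at t0, channel 1 at t1) sequences under the net's rounded
    binary gating and reports which outputs fired.  ``matches_expected``
    is true iff V fires output 0 only and D fires output 1 only.
    """
    if net.m != 2 or net.n != 2:
        raise ValueError(f"truth table requires a 2x2 net, got {net.m}x{net.n}")
    patterns = fixture_fig5() if patterns is None else patterns
    gating = GatingSample(get_binary_matrix(net))
    names = ("V", "D")
    table: dict = {}
    ok = True
    for k, (name, pattern) in enumerate(zip(names, patterns)):
        trace = propagate(net, gating, pattern)
        fired = sorted({out for out, _ in trace.output_spikes})
        table[name] = {
            "target_output": k,
            "fired": fired,
            "target_fired": k in fired,
            "off_target": [f for f in fired if f != k],
            "spikes": [list(s) for s in trace.output_spikes],
        }
        ok = ok and fired == [k]
    table["matches_expected"] = ok
    return table


def convergence_report(result: TrainingResult) -> dict:
    """Diagnostics of a training run.

    Reports presentation counts, per-layer convergence iterations and
    final temperatures; for a 2x2 net it additionally scans the recorded
    gating-change history for the presentation index at which the truth
    table first became (and stayed) stable.
    """
    net = result.network
    doc = {
        "m": net.m,
        "n": net.n,
        "converged": result.converged,
        "presentations_used": result.presentations_used,
        "layer_convergence_iteration": list(result.layer_convergence_iteration),
        "final_temperatures": net.temperatures.tolist(),
        "learning_events": len(result.events),
        "truth_table_stable_iteration": None,
    }
    if not result.converged:
        w = net.trainable
        if w.size:
            dist = np.minimum(w, 1.0 - w)
            doc["weight_distance_histogram"] = np.histogram(dist, bins=10, range=(0, 0.5))[
                0
            ].tolist()
    if net.m == 2 and net.n == 2 and result.config_change_history:
        from .netmodel import set_binary_config

        tables = []
        for _, bits in result.config_change_history:
            snap = set_binary_config(net, bits)
            t = truth_table(snap)
            tables.append({k: v for k, v in t.items() if k != "matches_expected"})
        final = tables[-1]
        stable = None
        for (pres, _), tab in zip(result.config_change_history, tables):
            if tab != final:
                stable = None
            elif stable is None:
                stable = pres
        doc["truth_table_stable_iteration"] = stable
        doc["truth_table"] = truth_table(net)
    return doc
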