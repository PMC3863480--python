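"""Cycle-accurate signal propagation and stochastic path gating.

The integer clock advances in unit steps (1 ms at the default scale).
Each input event injects a signal into its column at its event time; the
signal then transits one block segment per hop, taking 1 clock step on
the direct path and 2 on the delay path (the delay neuron adds exactly
one step).  Whether a given segment routes direct or delay for one
presentation is drawn once per presentation from the Boltzmann
path-selection probability

    P_direct = exp(w_direct/T) / (exp(w_direct/T) + exp(w_delay/T))

and the delay path is taken when the uniform draw is >= P_direct.  Output
neuron ``k`` reads layer ``k``: it spikes at the first clock step at
which the number of distinct columns holding a signal at layer ``k``
exceeds its threshold (a planar wave front); at most one spike per
output per presentation.  At high temperature the gating is near-random;
as T -> 0 it becomes the deterministic switch encoded by the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .netmodel import Network

__all__ = [
    "p_direct",
    "GatingSample",
    "sample_gating",
    "PropagationTrace",
    "propagate",
    "spiking_outputs",
    "decode",
    "AmbiguousDecodeError",
]


def p_direct(w_direct, w_delay, T):
    """Boltzmann probability of taking the direct path at one bifurcation.

    Computed as the logistic sigmoid of ``(w_direct - w_delay)/T``, which
    equals ``e^{w_direct/T} / (e^{w_direct/T} + e^{w_delay/T})`` and is
    overflow-safe at small T.  ``P_delay = 1 - P_direct``.
    """
    w_direct = np.asarray(w_direct, dtype=float)
    w_delay = np.asarray(w_delay, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("Boltzmann temperature must be > 0")
    if np.any((w_direct < 0) | (w_direct > 1) | (w_delay < 0) | (w_delay > 1)):
        raise ValueError("weights must lie in [0, 1]")
    out = expit((w_direct - w_delay) / T)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GatingSample:
    """One sampled binary routing decision per segment for one presentation.

    ``choices[i, l]`` is 1 if segment ``l`` of column ``i`` routes direct,
    0 if it routes via the delay neuron; the input-layer column is always
    all-direct.
    """

    choices: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.choices, dtype=np.uint8)
        if c.ndim != 2:
            raise ValueError("choices must be an m x n matrix")
        if not np.all(np.isin(c, (0, 1))):
            raise ValueError("choices must be binary")
        if not np.all(c[:, 0] == 1):
            raise ValueError("input-layer segments must route direct")
        object.__setattr__(self, "choices", c)

    @property
    def transit_steps(self) -> np.ndarray:
        """Per-segment transit time in clock steps (1 direct, 2 delay)."""
        return (2 - self.choices).astype(np.int64)


def sample_gating(net: Network, rng: np.random.Generator | None = None) -> GatingSample:
    """Draw one gating configuration from the current weights and temperatures.

    One uniform number is drawn per segment (including the clamped input
    layer, whose outcome is then overridden to direct — this keeps the
    consumed random stream independent of the clamp).  The delay path is
    chosen where the draw is >= P_direct.
    """
    rng = net.rng if rng is None else rng
    p = expit((net.w_direct - net.w_delay) / net.temperatures[np.newaxis, :])
    r = rng.random((net.m, net.n))
    choices = (r < p).astype(np.uint8)
    choices[:, 0] = 1
    return GatingSample(choices)


@dataclass(frozen=True)
class PropagationTrace:
    """Integer-clock record of one presentation.

    ``occupancy`` maps each clock step to the set of ``(column, layer)``
    positions holding a signal at that step; ``output_spikes`` lists
    ``(output_index, clock_step)`` events (at most one per output);
    ``first_input_time`` anchors the relative time of the place-time code.
    """

    occupancy: dict[int, frozenset[tuple[int, int]]]
    output_spikes: tuple[tuple[int, int], ...]
    first_input_time: int | None


class AmbiguousDecodeError(ValueError):
    """Raised when more than one distinct output neuron spiked."""

    def __init__(self, spikes: tuple[tuple[int, int], ...]):
        self.spikes = spikes
        super().__init__(
            f"ambiguous trace: outputs {sorted({k for k, _ in spikes})} all spiked"
        )


def _arrival_times(net: Network, gating: GatingSample, pattern) -> tuple[list, np.ndarray]:
    """Injected events (post-ablation) and their per-layer arrival times.

    Returns ``(events, arrivals)`` where ``arrivals[e, l]`` is the clock
    step at which the signal of event ``e`` occupies layer ``l``.
    """
    if pattern.width != net.m:
        raise ValueError(
            f"pattern width {pattern.width} does not match network m={net.m}"
        )
    events = [
        (i, t) for i, t in pattern.events if i not in net.ablated_columns
    ]
    if not events:
        return events, np.zeros((0, net.n), dtype=np.int64)
    steps = gating.transit_steps  # (m, n)
    # cumulative transit from layer 0 to layer l, per column
    cum = np.concatenate(
        [np.zeros((net.m, 1), dtype=np.int64), np.cumsum(steps[:, 1:], axis=1)], axis=1
    )
    cols = np.fromiter((i for i, _ in events), dtype=np.int64)
    times = np.fromiter((t for _, t in events), dtype=np.int64)
    return events, times[:, None] + cum[cols, :]


def _first_spikes(
    net: Network, events: list, arrivals: np.ndarray
) -> list[tuple[int, int]]:
    """First planar-wave-front coincidence per output, sorted by output index."""
    spikes: list[tuple[int, int]] = []
    if not events:
        return spikes
    cols = [i for i, _ in events]
    for k in range(net.n):
        per_time: dict[int, set[int]] = {}
        for e, c in enumerate(cols):
            per_time.setdefault(int(arrivals[e, k]), set()).add(c)
        hit = [t for t, cs in sorted(per_time.items()) if len(cs) > net.thresholds[k]]
        if hit:
            spikes.append((k, hit[0]))
    return spikes


def spiking_outputs(net: Network, gating: GatingSample, pattern) -> list[tuple[int, int]]:
    """Outputs that spike for one presentation, as ``(output_index, step)``.

    Equivalent to ``propagate(...).output_spikes`` without building the
    occupancy record; used by the training loop.
    """
    events, arrivals = _arrival_times(net, gating, pattern)
    return _first_spikes(net, events, arrivals)


def propagate(net: Network, gating: GatingSample, pattern) -> PropagationTrace:
    """Run one full presentation and record the complete trace.

    Deterministic given ``(gating, pattern)``.  Each signal occupies
    layer ``l`` for exactly the clock step of its arrival there.
    """
    events, arrivals = _arrival_times(net, gating, pattern)
    spikes = _first_spikes(net, events, arrivals)
    occupancy: dict[int, set[tuple[int, int]]] = {}
    for e, (i, _) in enumerate(events):
        for l in range(net.n):
            occupancy.setdefault(int(arrivals[e, l]), set()).add((i, l))
    frozen = {t: frozenset(s) for t, s in sorted(occupancy.items())}
    first = min((t for _, t in events), default=None)
    return PropagationTrace(
        occupancy=frozen, output_spikes=tuple(spikes), first_input_time=first
    )


def decode(trace: PropagationTrace) -> tuple[int, int] | None:
    """Time-and-place read-out of a trace.

    Returns ``(feature_index, relative_time)`` — which output neuron
    fired and when, relative to the first input event — or ``None`` for a
    silent trace.  A trace in which several distinct outputs fired is
    reported via :class:`AmbiguousDecodeError` rather than silently
    resolved.
    """
    if not trace.output_spikes:
        return None
    outputs = {k for k, _ in trace.output_spikes}
    if len(outputs) > 1:
        raise AmbiguousDecodeError(trace.output_spikes)
    k, t = trace.output_spikes[0]
    return k, t - (trace.first_input_time or 0)
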