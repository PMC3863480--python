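"""Stochastic Hebbian learning with per-layer Boltzmann annealing.

One presentation = draw a gating sample, propagate a training pattern,
and — if any output neuron spiked — reinforce the sampled routing of the
spiking layer: for every segment of that layer the selected path weight
moves a fraction ``alpha`` of its remaining distance toward 1 and the
deselected weight the same amount toward 0, keeping the antagonistic
pair complementary.  The spiking layer's Boltzmann temperature is then
lowered by ``delta_T`` (floored at ``T_min``), so successful layers cool
into deterministic gating.  When several outputs spike in the same
presentation, only the lowest-index spiking layer learns, which enforces
the bottom-up sequential settling of the layers: the first layer's
weights settle first, later layers are conditioned on the already-frozen
routing below them.  Training is unsupervised — any spike reinforces
whatever routing produced it — and finishes when every trainable weight
has converged to (within tolerance of) its 0/1 end state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .netmodel import Network, NetworkConfig
from .stimuli import PatternSet
from .dynamics import GatingSample, spiking_outputs

__all__ = [
    "update_weight",
    "anneal_layer",
    "is_converged",
    "TrainingResult",
    "train",
]


def update_weight(
    w_selected_old: float, w_deselected_old: float, alpha: float
) -> tuple[float, float]:
    """Complementary reinforcement of one antagonistic weight pair.

    ``w_sel <- w_sel + (1 - w_sel)*alpha`` and
    ``w_desel <- w_desel - w_desel*alpha``: the two increments sum to
    ``(1 - w_sel - w_desel)*alpha = 0`` for a complementary pair, so the
    pair stays complementary, and ``(1, 0)`` / ``(0, 1)`` are fixed
    points.  Results are clamped to ``[0, 1]``.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    w_sel = w_selected_old + (1.0 - w_selected_old) * alpha
    w_desel = w_deselected_old - w_deselected_old * alpha
    return min(max(w_sel, 0.0), 1.0), min(max(w_desel, 0.0), 1.0)


def anneal_layer(T_current: float, delta_T: float, T_min: float) -> float:
    """One annealing step: lower the layer temperature, floored at ``T_min``."""
    return max(T_current - delta_T, T_min)


def is_converged(net: Network, tol: float | None = None) -> bool:
    """True iff every trainable ``w_direct`` is within ``tol`` of 0 or 1.

    The clamped input layer is excluded (it is binary by construction);
    a net with no trainable segments (``n == 1``) is trivially converged.
    """
    tol = net.config.convergence_tol if tol is None else tol
    w = net.trainable
    if w.size == 0:
        return True
    return bool(np.all(np.minimum(w, 1.0 - w) <= tol))


def _layer_binarized(net: Network, layer: int, tol: float) -> bool:
    if layer == 0:
        return True
    w = net.w_direct[:, layer]
    return bool(np.all(np.minimum(w, 1.0 - w) <= tol))


@dataclass
class TrainingResult:
    """Outcome of one training run.

    ``layer_convergence_iteration[l]`` is the number of presentations
    after which layer ``l``'s weights were (and stayed) binarized, or
    ``None`` if the layer never settled; the clamped input layer settles
    at 0 by construction.  ``events`` records every learning event as
    ``(presentation, layer, temperature_after, mean |w - round(w)| of the
    layer)``.  ``config_change_history`` records the rounded gating
    matrix whenever it changed, as ``(presentations_completed, bits)``,
    starting with the initial state at 0.
    """

    network: Network
    presentations_used: int
    converged: bool
    layer_convergence_iteration: list[int | None]
    events: list[tuple[int, int, float, float]] = field(default_factory=list)
    config_change_history: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def temperature_history(self) -> list[list[tuple[int, float]]]:
        """Per layer, the ``(presentation, temperature)`` annealing sequence."""
        hist: list[list[tuple[int, float]]] = [[] for _ in range(self.network.n)]
        for p, layer, T, _ in self.events:
            hist[layer].append((p, T))
        return hist


def train(
    net: Network, patterns: PatternSet, config: NetworkConfig | None = None
) -> TrainingResult:
    """Run the presentation loop until all weights binarize or the cap hits.

    Patterns cycle round-robin (class 0, 1, ..., n-1, repeat) or in a
    seeded shuffled order if ``config.shuffle``.  The input network is
    not modified; the returned result holds the trained copy.
    Non-convergence at ``max_presentations`` is a reported outcome
    (``converged=False``), never an exception.  Deterministic given
    (network state, config, patterns).
    """
    if patterns.width != net.m:
        raise ValueError(
            f"pattern width {patterns.width} does not match network m={net.m}"
        )
    if len(patterns) != net.n:
        raise ValueError(
            f"pattern set has {len(patterns)} classes but network has n={net.n} outputs"
        )
    config = net.config if config is None else config
    net = net.copy()
    if config is not net.config:
        net.config = config
    tol = config.convergence_tol
    alpha = config.alpha

    layer_conv: list[int | None] = [
        (0 if _layer_binarized(net, l, tol) else None) for l in range(net.n)
    ]
    events: list[tuple[int, int, float, float]] = []
    last_bits = (net.w_direct > 0.5).astype(np.uint8)
    changes: list[tuple[int, np.ndarray]] = [(0, last_bits.copy())]

    if is_converged(net, tol):
        return TrainingResult(net, 0, True, layer_conv, events, changes)

    order = np.arange(net.n)
    presentations = 0
    converged = False
    for p in range(config.max_presentations):
        idx = p % net.n
        if idx == 0 and config.shuffle:
            order = net.rng.permutation(net.n)
        pattern = patterns[int(order[idx])]

        gating = _sample(net)
        spikes = spiking_outputs(net, gating, pattern)
        presentations = p + 1
        if not spikes:
            continue
        k = min(s for s, _ in spikes)  # sequential settling: lowest layer learns
        if k >= 1 and alpha > 0:
            w = net.w_direct[:, k]
            sel = gating.choices[:, k].astype(bool)
            w_new = np.where(sel, w + (1.0 - w) * alpha, w * (1.0 - alpha))
            net.w_direct[:, k] = np.clip(w_new, 0.0, 1.0)
        net.temperatures[k] = anneal_layer(
            net.temperatures[k], config.delta_T, config.T_min
        )
        mean_dist = float(
            np.mean(np.minimum(net.w_direct[:, k], 1.0 - net.w_direct[:, k]))
        )
        events.append((p, k, float(net.temperatures[k]), mean_dist))

        if k >= 1:
            if _layer_binarized(net, k, tol):
                if layer_conv[k] is None:
                    layer_conv[k] = presentations
            else:
                layer_conv[k] = None
            bits = (net.w_direct > 0.5).astype(np.uint8)
            if not np.array_equal(bits, last_bits):
                last_bits = bits
                changes.append((presentations, bits.copy()))
            if is_converged(net, tol):
                converged = True
                break

    return TrainingResult(net, presentations, converged, layer_conv, events, changes)


def _sample(net: Network) -> GatingSample:
    """Inline gating draw (identical stream to :func:`dynamics.sample_gating`)."""
    p = expit((2.0 * net.w_direct - 1.0) / net.temperatures[np.newaxis, :])
    r = net.rng.random((net.m, net.n))
    choices = (r < p).astype(np.uint8)
    choices[:, 0] = 1
    return GatingSample(choices)
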