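"""Perturbations for robustness studies: jitter, dropout, column ablation.

The clean simulator assumes perfectly timed, lossless input and an
intact lattice.  This module degrades those assumptions in controlled
ways: event times jittered by a uniform integer offset (zero-mean),
events dropped independently with a fixed probability, and whole delay
lines ablated (the column injects no signals; its stored weights are
untouched).  Lost columns can be compensated by lowering the output
thresholds, trading selectivity for fault tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netmodel import Network
from .stimuli import StimulusPattern

__all__ = ["PerturbationSpec", "perturb_pattern", "ablate_columns"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of one perturbation regime.

    ``jitter_steps`` is the maximum absolute timing shift (uniform
    integer on ``[-j, +j]``, clipped to the pattern duration);
    ``dropout_prob`` the per-event deletion probability;
    ``ablated_columns`` the delay lines to silence; ``threshold_offset``
    a non-positive shift applied to output thresholds on ablation.
    """

    jitter_steps: int = 0
    dropout_prob: float = 0.0
    ablated_columns: frozenset[int] = frozenset()
    threshold_offset: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.jitter_steps < 0:
            raise ValueError(f"jitter_steps must be >= 0, got {self.jitter_steps}")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError(f"dropout_prob must be in [0, 1], got {self.dropout_prob}")
        if self.threshold_offset > 0:
            raise ValueError("threshold_offset must be <= 0")
        object.__setattr__(
            self, "ablated_columns", frozenset(int(c) for c in self.ablated_columns)
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def perturb_pattern(
    pattern: StimulusPattern,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> StimulusPattern:
    """Apply dropout then jitter to a pattern's events.

    Events are visited in their canonical ``(time, channel)`` order; each
    draws one uniform number for dropout and, if kept, one integer
    offset for jitter (clipped into ``[0, duration-1]``).  Deterministic
    for a seeded ``rng`` (defaults to one built from ``spec.seed``).
    Coinciding jittered events merge (activations are idempotent), so
    the result can have fewer events than the source.
    """
    rng = spec.rng() if rng is None else rng
    kept: list[tuple[int, int]] = []
    j = spec.jitter_steps
    for i, t in pattern.events:
        if spec.dropout_prob > 0 and rng.random() < spec.dropout_prob:
            continue
        if j > 0:
            t = int(np.clip(t + int(rng.integers(-j, j + 1)), 0, pattern.duration - 1))
        kept.append((i, t))
    if not kept:
        # the all-dropped pattern keeps its frame but carries no events;
        # StimulusPattern requires none, which an empty tuple satisfies
        return StimulusPattern(
            width=pattern.width,
            duration=pattern.duration,
            events=(),
            label=pattern.label,
        )
    return StimulusPattern(
        width=pattern.width,
        duration=pattern.duration,
        events=tuple(kept),
        label=pattern.label,
    )


def ablate_columns(
    net: Network, columns, threshold_offset: int = 0
) -> Network:
    """Silence whole delay lines: ablated columns inject no signals.

    Returns a copy; stored weights are never altered — only signal
    injection and (optionally, via the non-positive
    ``threshold_offset``) the output thresholds.  Ablating every column
    is rejected.
    """
    columns = frozenset(int(c) for c in columns)
    if any(not 0 <= c < net.m for c in columns):
        raise ValueError(f"column indices must lie in [0, {net.m - 1}]")
    if threshold_offset > 0:
        raise ValueError("threshold_offset must be <= 0")
    merged = net.ablated_columns | columns
    if len(merged) == net.m:
        raise ValueError("cannot ablate all columns — no signal paths would remain")
    out = net.copy()
    out.ablated_columns = merged
    out.thresholds = net.thresholds + threshold_offset
    return out
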