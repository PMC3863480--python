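"""Reference solutions: analytic delay configuration and brute-force search.

The learned weight settings are claimed to be equivalent to the mapping
a Hough transform performs from pattern space to an ordered feature
space.  For bar patterns the mapping has a closed form derived here from
the coincidence condition: the signal of column ``i`` reaches layer
``k`` at time ``onset_i + k + (cumulative delay count of column i over
layers 1..k)``, so output ``k`` sees a planar wave front exactly when
every column's cumulative delay count compensates its input-onset skew
(``delay_count_i(k) = max_j onset_j(k) - onset_i(k)``).  Because the
skew of consecutive bar classes grows by at most one step per column,
the per-layer delay placement is forced (delta of the cumulative count,
0 = direct, 1 = delay); where slack exists, delays are placed as early
(with as small a uniform shift) as possible — the canonical form.

For small nets an exhaustive enumeration over all admissible binary
configurations serves as the independent oracle: a configuration is
feasible when every training pattern fires exactly its own output
neuron.  The analytic construction is verified by propagation before it
is returned, and is cross-checked against the enumeration in the test
suite.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np

from .netmodel import Network, NetworkConfig, build_network, set_binary_config
from .stimuli import PatternSet
from .dynamics import GatingSample, propagate, decode, AmbiguousDecodeError

__all__ = [
    "BinaryConfig",
    "FeasibleSet",
    "InfeasibleSkewError",
    "analytic_config",
    "brute_force_configs",
    "verify_config",
]

ENUMERATION_BOUND = 12  # free bits: brute force caps at 2**12 configurations


@dataclass(frozen=True)
class BinaryConfig:
    """An ``m x n`` binary gating matrix: 1 = direct path, 0 = delay path."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 2:
            raise ValueError("bits must be an m x n matrix")
        if not np.all(np.isin(b, (0, 1))):
            raise ValueError("bits must be binary")
        if not np.all(b[:, 0] == 1):
            raise ValueError("input-layer column must be all-direct")
        b.setflags(write=False)
        object.__setattr__(self, "bits", b)

    @property
    def m(self) -> int:
        return self.bits.shape[0]

    @property
    def n(self) -> int:
        return self.bits.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryConfig):
            return NotImplemented
        return np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.bits.tobytes() + bytes(self.bits.shape))


@dataclass(frozen=True)
class FeasibleSet:
    """All binary configurations that classify a training set perfectly."""

    configs: frozenset[BinaryConfig]
    m: int
    n: int
    pattern_set_id: str

    def __contains__(self, config: BinaryConfig) -> bool:
        return config in self.configs

    def __len__(self) -> int:
        return len(self.configs)


class InfeasibleSkewError(ValueError):
    """No delay placement can align the wave front for some (column, class)."""

    def __init__(self, column: int, klass: int, message: str):
        self.column = column
        self.klass = klass
        super().__init__(f"column {column}, class {klass}: {message}")


def _pattern_set_id(patterns: PatternSet) -> str:
    return hashlib.sha256(patterns.to_json().encode()).hexdigest()[:16]


def _deterministic_net(m: int, n: int, bits: np.ndarray) -> Network:
    net = build_network(m, n, NetworkConfig())
    return set_binary_config(net, bits)


def analytic_config(m: int, n: int, bars: PatternSet) -> BinaryConfig:
    """Closed-form delay configuration aligning every bar class.

    Requires single-onset-per-column patterns (the bar convention).  For
    each class ``k`` the cumulative delay count of column ``i`` over
    layers ``1..k`` must equal ``C_k - onset_i(k)`` for some uniform
    shift ``C_k >= max_i onset_i(k)``; consecutive classes must differ by
    0 or 1 delays per column or no placement exists
    (:class:`InfeasibleSkewError` names the offending column/class).
    The result is verified by propagation before being returned.
    """
    if len(bars) != n:
        raise ValueError(f"need {n} pattern classes, got {len(bars)}")
    if bars.width != m:
        raise ValueError(f"pattern width {bars.width} != m={m}")
    onsets = np.stack([p.onsets() for p in bars])  # (n_classes, m)

    bits = np.ones((m, n), dtype=np.uint8)
    cum = np.zeros(m, dtype=int)  # cumulative delays through layers 1..k-1
    skew0 = onsets[0].max() - onsets[0]
    if np.any(skew0 != 0):
        i = int(np.argmax(skew0 != 0))
        raise InfeasibleSkewError(
            i, 0, "class 0 is read at the clamped input layer and must have zero skew"
        )
    for k in range(1, n):
        base = (onsets[k].max() - onsets[k]) - cum
        shift = max(0, -int(base.min()))
        delta = base + shift
        if delta.min() < 0 or delta.max() > 1:
            i = int(np.argmax(delta) if delta.max() > 1 else np.argmin(delta))
            raise InfeasibleSkewError(
                i,
                k,
                f"required delay increment {int(delta[i])} at layer {k} "
                "is not 0 or 1 — skew exceeds the available layers",
            )
        bits[:, k] = 1 - delta.astype(np.uint8)
        cum += delta.astype(int)

    config = BinaryConfig(bits)
    report = verify_config(config, bars)
    if not report["pass"]:
        raise InfeasibleSkewError(
            -1, -1, f"constructed configuration failed verification: {report}"
        )
    return config


def brute_force_configs(m: int, n: int, patterns: PatternSet) -> FeasibleSet:
    """Enumerate every admissible configuration; keep the perfect classifiers.

    Admissible = input-layer column all-direct, all other segments free:
    ``2**(m*(n-1))`` candidates, bounded at ``2**12``.  A candidate is
    kept iff propagating every pattern ``k`` fires output ``k`` and no
    other output.
    """
    free = m * (n - 1)
    if free > ENUMERATION_BOUND:
        raise ValueError(
            f"enumeration bound exceeded: {free} free bits > {ENUMERATION_BOUND}"
        )
    if patterns.width != m or len(patterns) != n:
        raise ValueError("pattern set dimensions do not match (m, n)")
    template = build_network(m, n, NetworkConfig())
    feasible = set()
    for combo in itertools.product((0, 1), repeat=free):
        bits = np.ones((m, n), dtype=np.uint8)
        if free:
            bits[:, 1:] = np.asarray(combo, dtype=np.uint8).reshape(m, n - 1)
        config = BinaryConfig(bits)
        if _classifies_perfectly(template, config, patterns):
            feasible.add(config)
    return FeasibleSet(
        configs=frozenset(feasible), m=m, n=n, pattern_set_id=_pattern_set_id(patterns)
    )


def _classifies_perfectly(
    template: Network, config: BinaryConfig, patterns: PatternSet
) -> bool:
    net = set_binary_config(template, config.bits)
    gating = GatingSample(config.bits)
    for k, pattern in enumerate(patterns):
        trace = propagate(net, gating, pattern)
        try:
            decoded = decode(trace)
        except AmbiguousDecodeError:
            return False
        if decoded is None or decoded[0] != k:
            return False
    return True


def verify_config(config: BinaryConfig | np.ndarray, patterns: PatternSet) -> dict:
    """Propagate every pattern under a binary configuration and report.

    Returns ``{"pass": bool, "per_pattern": [...]}`` where each entry
    carries the decoded class (or ``"no_spike"`` / ``"ambiguous"``) and
    the spike time relative to the first input event.  Overall pass iff
    pattern ``k`` decodes to class ``k`` for every ``k``.
    """
    if not isinstance(config, BinaryConfig):
        config = BinaryConfig(np.asarray(config))
    net = _deterministic_net(config.m, config.n, config.bits)
    if patterns.width != net.m:
        raise ValueError("pattern width does not match configuration")
    gating = GatingSample(config.bits)
    per_pattern = []
    ok = True
    for k, pattern in enumerate(patterns):
        trace = propagate(net, gating, pattern)
        try:
            decoded = decode(trace)
        except AmbiguousDecodeError as exc:
            per_pattern.append(
                {"true_class": k, "decoded": "ambiguous",
                 "spikes": [list(s) for s in exc.spikes]}
            )
            ok = False
            continue
        if decoded is None:
            per_pattern.append({"true_class": k, "decoded": "no_spike"})
            ok = False
        else:
            per_pattern.append(
                {"true_class": k, "decoded": decoded[0], "relative_time": decoded[1],
                 "label": pattern.label}
            )
            ok = ok and decoded[0] == k
    return {"pass": ok, "per_pattern": per_pattern}
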