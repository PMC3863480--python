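"""Network structure: columns of block-segment microcircuits.

The net consists of ``m`` input neurons, ``m x n`` delay neurons and ``n``
output (feature classifier) neurons.  Each of the ``m`` parallel cortical
columns is a chain of ``n`` block segments; inside a segment the signal
path bifurcates into a direct path and a one-step delay path governed by
the antagonistic weight pair ``(w_direct, w_delay)`` with
``w_direct + w_delay = 1``.  Only ``w_direct`` is stored; ``w_delay`` is
derived.  Layer 0 (the input layer) is permanently clamped to the direct
path (``w_direct = 1``), wiring the input neurons straight to the first
output neuron.  Synapses onto the output neurons are hardwired with
weight 1 and never updated; an output neuron spikes when the number of
column signals arriving simultaneously at its layer exceeds its
threshold, which defaults to the number of signal paths minus one
(``m - 1``, i.e. all columns must coincide).

Each layer carries its own Boltzmann temperature, annealed from ``T_max``
down to ``T_min`` in constant decrements ``delta_T`` as learning
progresses (see :mod:`columnhough.plasticity`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "NetworkConfig",
    "Network",
    "build_network",
    "set_binary_config",
    "get_binary_matrix",
    "save_network",
    "load_network",
]

HARDWIRED_OUTPUT_WEIGHT = 1.0
_FORMAT = "columnhough-network"
_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Training hyperparameters and structural options.

    Attributes
    ----------
    T_max, T_min, delta_T
        Boltzmann annealing schedule: every layer starts at ``T_max`` and
        is lowered by ``delta_T`` (to a floor of ``T_min``) each time its
        output neuron triggers learning.
    alpha
        Learning slope parameter in ``[0, 1)``: the selected path weight
        moves a fraction ``alpha`` of its remaining distance toward 1,
        the deselected toward 0.  ``alpha = 0`` disables learning.
    seed
        Seed for the single named RNG driving all stochastic gating.
    max_presentations
        Cap on the training loop; hitting it is a reported outcome, not
        an error.
    convergence_tol
        A weight counts as binarized when within this distance of 0 or 1.
    threshold_offset
        Non-positive shift applied to every output threshold
        (``m - 1 + threshold_offset``); lowering thresholds trades
        selectivity for robustness to noise or lost delay lines.
    shuffle
        Present training patterns in seeded random order instead of
        round-robin.
    """

    T_max: float = 1.0
    T_min: float = 0.05
    delta_T: float = 0.005
    alpha: float = 0.01
    seed: int = 0
    max_presentations: int = 100_000
    convergence_tol: float = 1e-3
    threshold_offset: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        if not (self.T_max > self.T_min > 0):
            raise ValueError(
                f"need T_max > T_min > 0, got T_max={self.T_max}, T_min={self.T_min}"
            )
        if self.delta_T <= 0:
            raise ValueError(f"delta_T must be > 0, got {self.delta_T}")
        if not 0 <= self.alpha < 1:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0 < self.convergence_tol < 0.5:
            raise ValueError(
                f"convergence_tol must be in (0, 0.5), got {self.convergence_tol}"
            )
        if self.max_presentations < 0:
            raise ValueError("max_presentations must be >= 0")
        if self.threshold_offset > 0:
            raise ValueError(
                f"threshold_offset must be <= 0, got {self.threshold_offset}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError("config file must be a key-value mapping")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


class Network:
    """An ``m``-column, ``n``-layer delay-line network.

    Holds the primary weight matrix ``w_direct`` (shape ``(m, n)``,
    column-major in the anatomical sense: entry ``[i, l]`` is segment
    ``l`` of column ``i``), per-layer temperatures, per-output integer
    thresholds, the configuration and the shared RNG.
    """

    def __init__(
        self,
        m: int,
        n: int,
        w_direct: np.ndarray,
        temperatures: np.ndarray,
        thresholds: np.ndarray,
        config: NetworkConfig,
        rng: np.random.Generator,
        ablated_columns: frozenset[int] = frozenset(),
    ):
        self.m = int(m)
        self.n = int(n)
        self.w_direct = np.asarray(w_direct, dtype=float)
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.thresholds = np.asarray(thresholds, dtype=int)
        self.config = config
        self.rng = rng
        self.ablated_columns = frozenset(int(c) for c in ablated_columns)
        self._check()

    def _check(self) -> None:
        if self.w_direct.shape != (self.m, self.n):
            raise ValueError(
                f"w_direct shape {self.w_direct.shape} != ({self.m}, {self.n})"
            )
        if self.temperatures.shape != (self.n,):
            raise ValueError("temperatures must have one entry per layer")
        if self.thresholds.shape != (self.n,):
            raise ValueError("thresholds must have one entry per output")
        if np.any((self.w_direct < 0) | (self.w_direct > 1)):
            raise ValueError("weights must lie in [0, 1]")
        if not np.all(self.w_direct[:, 0] == 1.0):
            raise ValueError("input-layer segments must be clamped to the direct path")
        if any(not 0 <= c < self.m for c in self.ablated_columns):
            raise ValueError("ablated column index out of range")

    @property
    def w_delay(self) -> np.ndarray:
        """Derived antagonistic weights, ``1 - w_direct``."""
        return 1.0 - self.w_direct

    @property
    def trainable(self) -> np.ndarray:
        """View of the trainable weights (all layers past the clamped input layer)."""
        return self.w_direct[:, 1:]

    def copy(self) -> "Network":
        """Deep copy, including an exact clone of the RNG state."""
        rng = np.random.Generator(type(self.rng.bit_generator)())
        rng.bit_generator.state = self.rng.bit_generator.state
        return Network(
            self.m,
            self.n,
            self.w_direct.copy(),
            self.temperatures.copy(),
            self.thresholds.copy(),
            self.config,
            rng,
            self.ablated_columns,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.m == other.m
            and self.n == other.n
            and np.array_equal(self.w_direct, other.w_direct)
            and np.array_equal(self.temperatures, other.temperatures)
            and np.array_equal(self.thresholds, other.thresholds)
            and self.config == other.config
            and self.ablated_columns == other.ablated_columns
            and self.rng.bit_generator.state == other.rng.bit_generator.state
        )

    def __repr__(self) -> str:
        return (
            f"Network(m={self.m}, n={self.n}, "
            f"ablated={sorted(self.ablated_columns) or None})"
        )


def build_network(m: int, n: int, config: NetworkConfig | None = None) -> Network:
    """Construct a fresh network: ``m`` inputs, ``m*n`` delay neurons, ``n`` outputs.

    All trainable weight pairs start at the maximally undecided
    ``(0.5, 0.5)``; input-layer segments are clamped direct; every layer
    temperature starts at ``T_max``; thresholds default to ``m - 1``.
    """
    if m < 1 or n < 1:
        raise ValueError(f"network dimensions must be >= 1, got m={m}, n={n}")
    config = config or NetworkConfig()
    w = np.full((m, n), 0.5)
    w[:, 0] = 1.0
    temperatures = np.full(n, config.T_max)
    thresholds = np.full(n, m - 1 + config.threshold_offset, dtype=int)
    rng = np.random.default_rng(config.seed)
    return Network(m, n, w, temperatures, thresholds, config, rng)


def set_binary_config(net: Network, bits: np.ndarray) -> Network:
    """Return a copy of ``net`` with hard binary gating weights.

    ``bits`` is an ``m x n`` 0/1 matrix, 1 = direct, 0 = delay; the
    input-layer column must be all-direct.  With every weight at 0 or 1
    the gates act as deterministic switches.
    """
    bits = np.asarray(bits)
    if bits.shape != (net.m, net.n):
        raise ValueError(f"bits shape {bits.shape} != ({net.m}, {net.n})")
    if not np.all(np.isin(bits, (0, 1))):
        raise ValueError("bits must be 0 (delay) or 1 (direct)")
    if not np.all(bits[:, 0] == 1):
        raise ValueError("input-layer segments cannot be set to the delay path")
    out = net.copy()
    out.w_direct = bits.astype(float)
    return out


def get_binary_matrix(net: Network, tol: float = 0.5) -> np.ndarray:
    """Round the weight matrix to a 0/1 gating matrix.

    With the default ``tol = 0.5`` this is plain rounding; a tighter
    ``tol`` raises if any weight is farther than ``tol`` from both 0 and 1.
    """
    dist = np.minimum(net.w_direct, 1.0 - net.w_direct)
    if np.any(dist > tol):
        i, l = np.unravel_index(int(np.argmax(dist)), dist.shape)
        raise ValueError(
            f"weight at column {i}, layer {l} ({net.w_direct[i, l]:.4f}) "
            f"is not within {tol} of 0 or 1"
        )
    return (net.w_direct > 0.5).astype(np.uint8)


def save_network(net: Network, path: str | Path) -> None:
    """Serialize a network to a versioned JSON document (bit-exact round trip)."""
    state = net.rng.bit_generator.state
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "m": net.m,
        "n": net.n,
        "w_direct": [hex(np.float64(v).view(np.uint64).item()) for v in net.w_direct.ravel()],
        "temperatures": [
            hex(np.float64(v).view(np.uint64).item()) for v in net.temperatures
        ],
        "thresholds": net.thresholds.tolist(),
        "ablated_columns": sorted(net.ablated_columns),
        "config": net.config.to_dict(),
        "rng": {"bit_generator": state["bit_generator"], "state": state},
    }
    Path(path).write_text(json.dumps(doc, indent=1, default=int))


def _floats_from_hex(values: Iterable[str]) -> np.ndarray:
    return np.array(
        [np.uint64(int(v, 16)).view(np.float64) for v in values], dtype=float
    )


def load_network(path: str | Path) -> Network:
    """Load a network saved by :func:`save_network`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed network document {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise ValueError(f"{path} is not a {_FORMAT} document")
    if doc.get("version") != _VERSION:
        raise ValueError(
            f"unsupported network document version {doc.get('version')!r} "
            f"(expected {_VERSION})"
        )
    m, n = doc["m"], doc["n"]
    w = _floats_from_hex(doc["w_direct"]).reshape(m, n)
    temps = _floats_from_hex(doc["temperatures"])
    config = NetworkConfig.from_dict(doc["config"])
    bitgen_name = doc["rng"]["state"]["bit_generator"]
    bitgen = getattr(np.random, bitgen_name)()
    state = doc["rng"]["state"]
    # JSON round-trips PCG64 state integers losslessly (python ints are unbounded)
    bitgen.state = state
    rng = np.random.Generator(bitgen)
    return Network(
        m,
        n,
        w,
        temps,
        np.asarray(doc["thresholds"], dtype=int),
        config,
        rng,
        frozenset(doc["ablated_columns"]),
    )
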