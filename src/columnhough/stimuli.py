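"""Spatiotemporal stimulus generation.

Training and test patterns are binary images of ``m`` input channels by
``n`` clock steps, presented to the network row by row: at clock step ``t``
every active pixel of row ``t`` fires its input channel.  A bar of slope
0° is a single fully active row (all channels simultaneously); a 45° bar
activates channel ``i`` at step ``i``.  Intermediate slopes follow a
staircase rasterization: channel ``i`` fires at ``round(i*k/(m-1))``
(half-up rounding), which reproduces the horizontal and diagonal
endpoints and gives a monotone onset skew in the class index ``k``.

The module also provides the two canonical fixtures — the nine-bar 9x9
training set and the two-electrode vertical/diagonal pair used for MEA
(microelectrode array) stimulation — and an exporter that flattens a
pattern set into a chronological stimulation timeline ("played like a
piano"): one row per electrode event with an absolute time in
milliseconds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusPattern",
    "PatternSet",
    "make_bar_pattern",
    "make_sinusoid_pattern",
    "make_bar_set",
    "make_sinusoid_set",
    "fixture_fig3",
    "fixture_fig5",
    "export_mea_protocol",
]


def _round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StimulusPattern:
    """A binary spatiotemporal pattern.

    Parameters
    ----------
    width
        Number of input channels ``m``.
    duration
        Number of clock steps the pattern spans.
    events
        Active cells as ``(input_index, time_step)`` pairs, 0-based.
        Normalized on construction: deduplicated and sorted by
        ``(time_step, input_index)``; duplicate activations are idempotent.
    label
        Pattern class label — slope in degrees for bars, cycles per grid
        for sinusoids.
    """

    width: int
    duration: int
    events: tuple[tuple[int, int], ...]
    label: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.duration < 1:
            raise ValueError(f"duration must be >= 1, got {self.duration}")
        norm = sorted({(int(i), int(t)) for i, t in self.events})
        for i, t in norm:
            if not 0 <= i < self.width:
                raise ValueError(
                    f"event input index {i} outside [0, {self.width - 1}]"
                )
            if not 0 <= t < self.duration:
                raise ValueError(
                    f"event time step {t} outside [0, {self.duration - 1}]"
                )
        object.__setattr__(
            self, "events", tuple((i, t) for t, i in sorted((t, i) for i, t in norm))
        )

    @property
    def image(self) -> np.ndarray:
        """Equivalent binary raster, shape ``(duration, width)`` (rows = time)."""
        img = np.zeros((self.duration, self.width), dtype=bool)
        for i, t in self.events:
            img[t, i] = True
        return img

    @classmethod
    def from_image(cls, image: np.ndarray, label: float) -> "StimulusPattern":
        """Build a pattern from a binary raster (rows = time steps)."""
        img = np.asarray(image, dtype=bool)
        if img.ndim != 2:
            raise ValueError("image must be 2-D (duration x width)")
        ts, cols = np.nonzero(img)
        events = tuple((int(i), int(t)) for i, t in zip(cols, ts))
        return cls(width=img.shape[1], duration=img.shape[0], events=events, label=label)

    @property
    def first_event_time(self) -> int | None:
        return self.events[0][1] if self.events else None

    def onsets(self) -> np.ndarray:
        """Per-column activation time; requires exactly one event per column.

        Raises ``ValueError`` for patterns that are not single-onset per
        column (the bar convention the analytic solver relies on).
        """
        times: dict[int, int] = {}
        for i, t in self.events:
            if i in times:
                raise ValueError(f"column {i} has more than one event")
            times[i] = t
        if len(times) != self.width:
            missing = sorted(set(range(self.width)) - set(times))
            raise ValueError(f"columns {missing} have no event")
        return np.array([times[i] for i in range(self.width)], dtype=int)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "events": [[i, t] for i, t in self.events],
        }


@dataclass(frozen=True)
class PatternSet:
    """An ordered set of patterns, one per feature class ``k = 0..n-1``.

    All patterns share ``width`` and ``duration``; labels are strictly
    increasing with the class index (ascending slope / frequency, matching
    the bottom-to-top ordering of the feature classifier column).
    """

    patterns: tuple[StimulusPattern, ...]
    kind: str = "bars"

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("pattern set must contain at least one pattern")
        if self.kind not in ("bars", "sinusoids"):
            raise ValueError(f"kind must be 'bars' or 'sinusoids', got {self.kind!r}")
        object.__setattr__(self, "patterns", tuple(self.patterns))
        w, d = self.patterns[0].width, self.patterns[0].duration
        for p in self.patterns:
            if p.width != w or p.duration != d:
                raise ValueError("all patterns must share width and duration")
        labels = [p.label for p in self.patterns]
        if any(b <= a for a, b in zip(labels, labels[1:])):
            raise ValueError("labels must be strictly increasing with class index")

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, k: int) -> StimulusPattern:
        return self.patterns[k]

    def __iter__(self):
        return iter(self.patterns)

    @property
    def width(self) -> int:
        return self.patterns[0].width

    @property
    def duration(self) -> int:
        return self.patterns[0].duration

    @property
    def labels(self) -> list[float]:
        return [p.label for p in self.patterns]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "kind": self.kind,
            "width": self.width,
            "duration": self.duration,
            "patterns": [p.to_dict() for p in self.patterns],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatternSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        pats = tuple(
            StimulusPattern(
                width=doc["width"],
                duration=doc["duration"],
                events=tuple((int(i), int(t)) for i, t in d["events"]),
                label=float(d["label"]),
            )
            for d in doc["patterns"]
        )
        return cls(patterns=pats, kind=doc["kind"])


def make_bar_pattern(m: int, n: int, k: int) -> StimulusPattern:
    """Bar of class ``k`` on an ``m``-channel, ``n``-step grid.

    Channel ``i`` fires at step ``round(i*k/(m-1))`` (half-up).  Class 0 is
    the horizontal bar (all channels at step 0); with ``m == n``, class
    ``n-1`` is the 45° diagonal (channel ``i`` at step ``i``).  The label is
    the geometric slope angle ``atan(k/(m-1))`` in degrees.
    """
    if m < 2:
        raise ValueError(f"m must be >= 2 (need at least two channels), got {m}")
    if not 0 <= k < n:
        raise ValueError(f"class index k={k} outside [0, {n - 1}]")
    events = tuple((i, _round_half_up(i * k / (m - 1))) for i in range(m))
    label = math.degrees(math.atan2(k, m - 1))
    return StimulusPattern(width=m, duration=n, events=events, label=label)


def make_sinusoid_pattern(
    m: int,
    n: int,
    frequency: float,
    phase: float = 0.0,
    amplitude: float | None = None,
) -> StimulusPattern:
    """Discretized sinusoid: one active channel per clock step.

    The active channel at step ``t`` is
    ``round(c + a*sin(2*pi*frequency*t/n + phase))`` with center
    ``c = (m-1)/2`` and amplitude ``a`` (default ``(m-1)/2``), clipped to
    ``[0, m-1]``.  ``frequency`` is in cycles per grid (per ``n`` steps).
    The rounding/clipping discretization is this simulator's convention.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    c = (m - 1) / 2.0
    a = c if amplitude is None else float(amplitude)
    events = []
    for t in range(n):
        x = c + a * math.sin(2.0 * math.pi * frequency * t / n + phase)
        i = min(max(_round_half_up(x), 0), m - 1)
        events.append((i, t))
    return StimulusPattern(width=m, duration=n, events=tuple(events), label=frequency)


def make_bar_set(m: int, n: int) -> PatternSet:
    """All ``n`` bar classes on an m x n grid."""
    return PatternSet(tuple(make_bar_pattern(m, n, k) for k in range(n)), kind="bars")


def make_sinusoid_set(
    m: int, n: int, frequencies: Sequence[float] | None = None
) -> PatternSet:
    """Sinusoid classes at strictly increasing frequencies (default 1..n)."""
    if frequencies is None:
        frequencies = [float(f) for f in range(1, n + 1)]
    return PatternSet(
        tuple(make_sinusoid_pattern(m, n, f) for f in frequencies), kind="sinusoids"
    )


def fixture_fig3() -> PatternSet:
    """The canonical nine-bar training set on a 9x9 grid (classes 0..8)."""
    return make_bar_set(9, 9)


def fixture_fig5() -> PatternSet:
    """The two-electrode MEA stimulation pair.

    Class 0 (V, "vertical" bar): electrodes 1 and 2 fire in parallel at
    ``t0``.  Class 1 (D, diagonal bar): electrode 2 fires at ``t0``,
    electrode 1 at the consecutive step ``t1`` — paired-pulse stimulation
    over two adjacent electrodes, like playing a piano with two fingers.
    """
    v = StimulusPattern(width=2, duration=2, events=((0, 0), (1, 0)), label=0.0)
    d = StimulusPattern(width=2, duration=2, events=((1, 0), (0, 1)), label=45.0)
    return PatternSet((v, d), kind="bars")


def export_mea_protocol(
    pattern_set: PatternSet,
    inter_pattern_gap: int,
    repetitions: int,
    clock_ms: float,
) -> pd.DataFrame:
    """Flatten a pattern set into a chronological stimulation timeline.

    Patterns are presented in class order, each followed by
    ``inter_pattern_gap`` silent clock steps, the whole block repeated
    ``repetitions`` times; one clock step lasts ``clock_ms`` milliseconds
    (the delay surcharge of one delay neuron at the default 1 ms/step).

    Returns a DataFrame with columns ``channel``, ``time_ms``,
    ``pattern_id``, ``repetition``, sorted chronologically; total row
    count is ``repetitions * sum(len(p.events))``.
    """
    if len(pattern_set) == 0:
        raise ValueError("cannot export an empty pattern set")
    if inter_pattern_gap < 0:
        raise ValueError(f"inter_pattern_gap must be >= 0, got {inter_pattern_gap}")
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    if clock_ms <= 0:
        raise ValueError(f"clock_ms must be > 0, got {clock_ms}")

    rows = []
    step = 0
    for rep in range(repetitions):
        for pid, pat in enumerate(pattern_set):
            for i, t in pat.events:
                rows.append((i, (step + t) * clock_ms, pid, rep))
            step += pat.duration + inter_pattern_gap
    df = pd.DataFrame(rows, columns=["channel", "time_ms", "pattern_id", "repetition"])
    return df.sort_values(["time_ms", "channel"], kind="stable").reset_index(drop=True)


def write_protocol(df: pd.DataFrame, csv_path: str | Path | None = None,
                   json_path: str | Path | None = None) -> None:
    """Write an exported protocol table to CSV and/or an equivalent JSON document."""
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {"events": df.to_dict(orient="records")}
        Path(json_path).write_text(json.dumps(doc, indent=1))
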