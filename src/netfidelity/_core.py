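"""Shared containers for MEA recordings.

An :class:`ElectrodeLayout` describes where each electrode sits on the array
(positions in micrometres); a :class:`SpikeTrain` is the sorted spike times of
one unit anchored to an electrode; a :class:`Recording` bundles the trains of
one array with its layout and duration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeLayout", "SpikeTrain", "Recording"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode positions of a planar multielectrode array.

    Parameters
    ----------
    electrode_ids
        Integer label per electrode.
    x, y
        Positions in micrometres, aligned with ``electrode_ids``.
    rows, cols
        Grid dimensions (0 when the layout is not a regular grid).
    pitch
        Inter-electrode spacing in micrometres.
    """

    electrode_ids: tuple[int, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    rows: int = 0
    cols: int = 0
    pitch: float = 500.0

    def __post_init__(self) -> None:
        if not (len(self.electrode_ids) == len(self.x) == len(self.y)):
            raise ValueError("electrode_ids, x and y must have equal length")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        pos = set(zip(self.x, self.y))
        if len(pos) != len(self.electrode_ids):
            raise ValueError("electrode positions must be distinct")
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("electrode ids must be distinct")

    @classmethod
    def grid(cls, rows: int = 10, cols: int = 6, pitch: float = 500.0) -> "ElectrodeLayout":
        """Regular grid layout; default is the 6-column x 10-row, 500 um MEA."""
        ids, xs, ys = [], [], []
        for r in range(rows):
            for c in range(cols):
                ids.append(r * cols + c)
                xs.append(c * pitch)
                ys.append(r * pitch)
        return cls(tuple(ids), tuple(xs), tuple(ys), rows=rows, cols=cols, pitch=pitch)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def position(self, electrode_id: int) -> tuple[float, float]:
        i = self.electrode_ids.index(electrode_id)
        return self.x[i], self.y[i]

    def distance_um(self, a: int, b: int) -> float:
        """Euclidean distance between two electrodes, in micrometres."""
        xa, ya = self.position(a)
        xb, yb = self.position(b)
        return float(np.hypot(xa - xb, ya - yb))


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit, strictly increasing, in seconds."""

    unit_id: int
    electrode_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)

    def rate(self, duration: float) -> float:
        return self.n / duration


@dataclass
class Recording:
    """All spike trains of one array together with its layout and duration."""

    trains: list[SpikeTrain]
    layout: ElectrodeLayout
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.layout.electrode_ids)
        for tr in self.trains:
            if tr.electrode_id not in known:
                raise ValueError(
                    f"train {tr.unit_id} references unknown electrode {tr.electrode_id}"
                )
            if tr.n and tr.times[-1] > self.duration:
                raise ValueError(
                    f"train {tr.unit_id} has spikes beyond the recording duration"
                )

    @property
    def unit_ids(self) -> list[int]:
        return [tr.unit_id for tr in self.trains]

    def train(self, unit_id: int) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)
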