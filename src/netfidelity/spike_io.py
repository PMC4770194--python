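"""Recording I/O, threshold spike detection, and PCA + k-means unit sorting.

CSV dialects match the simulator's writers: spike tables with header
``unit_id,electrode_id,time_s`` and layouts with ``electrode_id,x_um,y_um``.
Spike detection follows the standard extracellular convention: events are
negative-going crossings of a threshold at five noise standard deviations,
with the noise SD estimated robustly as ``median(|x|)/0.6745``.  Units are
separated by projecting each +/-1 ms waveform onto its first three principal
components and clustering with k-means, choosing k by silhouette score.
Units firing below 0.1 Hz are discarded before analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._core import ElectrodeLayout, Recording, SpikeTrain

__all__ = [
    "SpikeTrain",
    "Recording",
    "DetectionConfig",
    "detect_spikes",
    "sort_units",
    "filter_low_rate",
    "read_recording",
    "write_recording",
    "read_layout",
    "write_layout",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Threshold-detection parameters.

    ``threshold_mult`` is the multiple of the noise SD (default 5);
    ``waveform_window_ms`` the half-width of the extracted waveform around a
    crossing; ``min_rate`` the inclusion threshold in Hz.
    ``polarity`` is "negative" (default) or "absolute".
    """

    threshold_mult: float = 5.0
    waveform_window_ms: float = 1.0
    sampling_rate: float = 25_000.0
    min_rate: float = 0.1
    max_units_per_electrode: int = 3
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.threshold_mult <= 0:
            raise ValueError("threshold_mult must be positive")
        if self.min_rate < 0:
            raise ValueError("min_rate must be non-negative")
        if self.polarity not in ("negative", "absolute"):
            raise ValueError("polarity must be 'negative' or 'absolute'")


def noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD estimate, median(|x|)/0.6745 (Gaussian-consistent)."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    trace: np.ndarray, config: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect threshold crossings in a raw voltage trace.

    Returns ``(times_s, waveforms)`` where each waveform holds the samples
    within one window half-width on either side of the crossing (zero-padded
    at the trace edges).  After each detected crossing, one full waveform
    window of dead time suppresses re-triggering on the same event.
    """
    if config is None:
        config = DetectionConfig()
    trace = np.asarray(trace, dtype=float)
    half = int(round(config.waveform_window_ms * 1e-3 * config.sampling_rate))
    if trace.size == 0:
        raise ValueError("empty trace")
    if trace.size < 2 * half + 1:
        raise ValueError("trace shorter than the waveform window")
    sd = noise_sd(trace)
    if sd == 0:
        raise ValueError("degenerate trace: zero noise SD")
    thr = config.threshold_mult * sd

    if config.polarity == "negative":
        below = trace < -thr
    else:
        below = np.abs(trace) > thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.concatenate([[0], crossings])

    # dead time of one full window after each kept crossing
    dead = 2 * half
    kept: list[int] = []
    last = -dead - 1
    for i in crossings:
        if i - last > dead:
            kept.append(int(i))
            last = i

    times = np.array(kept, dtype=float) / config.sampling_rate
    waveforms = np.zeros((len(kept), 2 * half + 1))
    for row, i in enumerate(kept):
        lo, hi = i - half, i + half + 1
        src = trace[max(lo, 0): min(hi, trace.size)]
        waveforms[row, max(0, -lo): max(0, -lo) + src.size] = src
    return times, waveforms


def sort_units(
    waveforms: np.ndarray, max_units: int = 3, seed: int = 0
) -> np.ndarray:
    """Partition waveforms into putative units.

    Projects onto the first three principal components and runs k-means for
    k = 2..max_units, selecting the k with the best silhouette score; a best
    silhouette below 0.5 (or degenerate input) collapses to a single unit.
    Deterministic given ``seed``.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    n = waveforms.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    if n < max_units:
        raise ValueError(f"need at least {max_units} waveforms for up to {max_units} units")
    if max_units < 2 or np.allclose(waveforms, waveforms[0]):
        return np.zeros(n, dtype=int)

    n_comp = min(3, n, waveforms.shape[1])
    feats = PCA(n_components=n_comp, random_state=seed).fit_transform(waveforms)
    if np.allclose(feats, 0):
        return np.zeros(n, dtype=int)

    best_labels, best_score = None, -np.inf
    for k in range(2, max_units + 1):
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
        if len(set(km.labels_)) < 2:
            continue
        score = silhouette_score(feats, km.labels_)
        if score > best_score:
            best_score, best_labels = score, km.labels_
    if best_labels is None or best_score < 0.5:
        return np.zeros(n, dtype=int)
    return np.asarray(best_labels, dtype=int)


def filter_low_rate(recording: Recording, min_rate: float = 0.1) -> Recording:
    """Drop units firing below ``min_rate`` Hz (default 0.1), preserving order."""
    if recording.duration <= 0:
        raise ValueError("recording duration must be positive")
    kept = [tr for tr in recording.trains
            if tr.n / recording.duration >= min_rate]
    if not kept:
        logger.warning("all %d trains fall below %.3g Hz", len(recording.trains), min_rate)
    return Recording(trains=kept, layout=recording.layout,
                     duration=recording.duration, metadata=dict(recording.metadata))


# ---------------------------------------------------------------------------
# CSV round trip


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    pd.DataFrame({"electrode_id": layout.electrode_ids,
                  "x_um": layout.x, "y_um": layout.y}).to_csv(path, index=False)


def read_layout(path: str | Path, rows: int = 0, cols: int = 0,
                pitch: float = 500.0) -> ElectrodeLayout:
    df = pd.read_csv(path)
    return ElectrodeLayout(tuple(int(e) for e in df["electrode_id"]),
                           tuple(float(x) for x in df["x_um"]),
                           tuple(float(y) for y in df["y_um"]),
                           rows=rows, cols=cols, pitch=pitch)


def write_recording(recording: Recording, spikes_path: str | Path,
                    layout_path: str | Path | None = None) -> None:
    rows = []
    for tr in recording.trains:
        for t in tr.times:
            rows.append((tr.unit_id, tr.electrode_id, t))
    pd.DataFrame(rows, columns=["unit_id", "electrode_id", "time_s"]).to_csv(
        spikes_path, index=False, float_format="%.9f")
    if layout_path is not None:
        write_layout(recording.layout, layout_path)


def read_recording(spikes_path: str | Path, layout: ElectrodeLayout | str | Path,
                   duration: float, metadata: dict | None = None) -> Recording:
    """Read a spike table against a layout; times are sorted if needed (with a
    warning) and an unknown electrode id raises naming the offender."""
    if not isinstance(layout, ElectrodeLayout):
        layout = read_layout(layout)
    df = pd.read_csv(spikes_path)
    known = set(layout.electrode_ids)
    trains = []
    for (uid, eid), grp in df.groupby(["unit_id", "electrode_id"], sort=True):
        if int(eid) not in known:
            raise ValueError(f"spike table references unknown electrode_id {int(eid)}")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            logger.warning("unsorted spike times for unit %s; sorting", uid)
            times = np.sort(times)
        times = np.unique(times)
        trains.append(SpikeTrain(unit_id=int(uid), electrode_id=int(eid), times=times))
    trains.sort(key=lambda tr: tr.unit_id)
    return Recording(trains=trains, layout=layout, duration=duration,
                     metadata=metadata or {})
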