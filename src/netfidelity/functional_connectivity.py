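"""Directed functional connectivity by scaled cross-correlation (SCA).

Cross-correlograms of bursty cultures are distorted by burst-induced
non-stationarity; SCA sidesteps this by computing Pearson correlations of
1 ms-binned spike counts inside short (20 ms) quasi-stationary segments and
averaging the per-segment coefficients at each lag over a +/-100 ms lag span.
A lag bin is significant when a one-sided one-sample t-test on the
Fisher-z-transformed per-segment correlations rejects zero correlation
(tested only where at least ``min_segments`` segments are valid: segment
correlations of sparse trains are lumpy and skewed, so the t-test needs a
few dozen samples to hold its level); a
candidate peak requires at least three consecutive significant lag bins with
positive mean correlation, and additionally must rise at least ``peak_z``
robust standard deviations above the correlogram's own noise floor
(median/MAD across lags), the standard amplitude criterion for correlogram
peaks.  Edges whose peak coefficient falls below ``min_weight`` are dropped
(weak-edge thresholding: a direct connection's peak amplitude is set by the
transmission physics, whereas indirect correlations are systematically
weaker, so an absolute floor is robust to recording length).  A run that spans both lag signs reflects reciprocal transmission and
yields one candidate per direction (the maximum over each sign).  Candidate
peaks whose implied conduction velocity (electrode distance over lag) falls
outside 0.1-0.8 m/s are discarded.  Surviving peaks form a
directed multigraph weighted by the peak Pearson coefficient; reciprocal
pairs collapse, in the undirected projection, to one link carrying the mean
of the two directional weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from ._core import Recording, SpikeTrain
from .synthetic_data import TopologyGroundTruth

__all__ = [
    "ConnectivityConfig",
    "Correlogram",
    "FunctionalEdge",
    "FunctionalGraph",
    "bin_train",
    "scaled_correlation",
    "pair_correlogram",
    "significant_run_peaks",
    "velocity_filter",
    "build_graph",
    "score_against_truth",
]

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityConfig:
    """SCA parameters: bin and segment sizes in ms, lag span, run criterion,
    per-bin significance level, and the admissible conduction-velocity range
    in m/s."""

    bin_ms: float = 1.0
    segment_ms: float = 20.0
    max_lag_ms: float = 100.0
    min_run: int = 3
    alpha: float = 0.05
    peak_z: float = 2.25
    min_weight: float = 0.06
    velocity_range: tuple[float, float] = (0.1, 0.8)
    min_segments: int = 30

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        ratio = self.segment_ms / self.bin_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("segment_ms must be a multiple of bin_ms")
        if self.max_lag_ms < self.segment_ms:
            raise ValueError("max_lag_ms must be at least segment_ms")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def seg_bins(self) -> int:
        return int(round(self.segment_ms / self.bin_ms))

    @property
    def max_lag_bins(self) -> int:
        return int(round(self.max_lag_ms / self.bin_ms))


@dataclass
class Correlogram:
    """Scaled correlation per lag with per-lag significance flags."""

    lags_ms: np.ndarray
    r: np.ndarray            # mean per-segment Pearson r per lag (NaN if undefined)
    significant: np.ndarray  # bool per lag
    n_segments: np.ndarray   # number of valid segments per lag


@dataclass(frozen=True)
class FunctionalEdge:
    """A directed functional connection: ``source`` leads ``target`` by
    ``lag_ms`` > 0; weight is the peak Pearson coefficient of the run."""

    source: int
    target: int
    lag_ms: float
    weight: float
    distance_um: float


@dataclass
class FunctionalGraph:
    """Directed multigraph of functional connections and its undirected
    pair-level projection (reciprocal links averaged)."""

    directed: nx.MultiDiGraph
    undirected: nx.Graph = field(init=False)

    def __post_init__(self) -> None:
        und = nx.Graph()
        und.add_nodes_from(self.directed.nodes(data=True))
        # pair-level directed weights: peak r over parallel edges
        pair_w: dict[tuple[int, int], float] = {}
        pair_lag: dict[tuple[int, int], float] = {}
        for u, v, data in self.directed.edges(data=True):
            key = (u, v)
            if key not in pair_w or data["weight"] > pair_w[key]:
                pair_w[key] = data["weight"]
                pair_lag[key] = data["lag_ms"]
        for (u, v), w in pair_w.items():
            if und.has_edge(u, v):
                continue
            back = pair_w.get((v, u))
            weight = w if back is None else 0.5 * (w + back)
            und.add_edge(u, v, weight=weight, reciprocal=back is not None)
        self.undirected = und

    @property
    def pair_directed(self) -> nx.DiGraph:
        """Binary pair-level directed graph (multiplicity collapsed)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.directed.nodes(data=True))
        for u, v, data in self.directed.edges(data=True):
            if not g.has_edge(u, v) or data["weight"] > g[u][v]["weight"]:
                g.add_edge(u, v, **data)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"src_unit": u, "dst_unit": v, "lag_ms": d["lag_ms"],
             "weight_r": d["weight"], "distance_um": d["distance_um"]}
            for u, v, d in self.directed.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["src_unit", "dst_unit", "lag_ms",
                                           "weight_r", "distance_um"])


# ---------------------------------------------------------------------------
# binning and scaled correlation


def bin_train(train: SpikeTrain | np.ndarray, bin_ms: float,
              duration_s: float) -> np.ndarray:
    """Spike counts in half-open bins [k*bin, (k+1)*bin); spikes at exactly
    ``duration`` are excluded, so the counts sum to the in-range spike count."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    nbins = int(np.ceil(duration_s * 1e3 / bin_ms))
    if times.size == 0:
        return np.zeros(nbins, dtype=np.int64)
    idx = np.floor(times * 1e3 / bin_ms).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < nbins)]
    return np.bincount(idx, minlength=nbins).astype(np.int64)


def _segment_r_matrix(a: np.ndarray, b: np.ndarray, seg: int, max_lag: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment Pearson r at every non-negative lag.

    Segments are anchored to the absolute bin grid; only segments fully inside
    the overlap at every lag are used so all lags see the same segment set.
    Returns (r_matrix [n_active, max_lag+1] with NaN where either window has
    zero variance, active_segment_indices).
    """
    n = min(a.size, b.size)
    n_seg = (n - max_lag) // seg
    if n_seg <= 0:
        return np.empty((0, max_lag + 1)), np.empty(0, dtype=int)
    A = a[: n_seg * seg].reshape(n_seg, seg).astype(np.float64)
    sa = A.sum(1)
    saa = (A * A).sum(1)
    var_a = seg * saa - sa * sa
    active = np.flatnonzero(var_a > 0)
    if active.size == 0:
        return np.empty((0, max_lag + 1)), active
    gather = active[:, None] * seg + np.arange(seg + max_lag)[None, :]
    B = b[gather].astype(np.float64)
    win = sliding_window_view(B, seg, axis=1)          # (m, max_lag+1, seg)
    sb = win.sum(-1)
    sbb = np.einsum("mls,mls->ml", win, win)
    sab = np.einsum("ms,mls->ml", A[active], win)
    num = seg * sab - sa[active, None] * sb
    den_sq = var_a[active, None] * (seg * sbb - sb * sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den_sq > 0, num / np.sqrt(np.where(den_sq > 0, den_sq, 1.0)),
                     np.nan)
    return r, active


def scaled_correlation(a_binned: np.ndarray, b_binned: np.ndarray,
                       config: ConnectivityConfig, lag_bins: int
                       ) -> tuple[float, np.ndarray]:
    """Scaled correlation of two binned trains at one lag (in bins).

    Correlates ``a[k]`` with ``b[k + lag]``; a negative lag evaluates the
    mirrored direction, so r_ab(+lag) == r_ba(-lag) by construction.  Returns
    the mean per-segment Pearson r over segments where both windows have
    nonzero variance, together with those per-segment values; with no valid
    segment the mean is NaN.
    """
    if abs(lag_bins) > config.max_lag_bins:
        raise ValueError("lag outside the configured lag span")
    if lag_bins < 0:
        return scaled_correlation(b_binned, a_binned, config, -lag_bins)
    a = np.asarray(a_binned, dtype=float)
    b = np.asarray(b_binned, dtype=float)
    if a.size != b.size:
        raise ValueError("binned trains must have equal length")
    seg = config.seg_bins
    r_mat, _ = _segment_r_matrix(a, b, seg, config.max_lag_bins)
    col = r_mat[:, lag_bins] if r_mat.size else np.empty(0)
    valid = col[np.isfinite(col)]
    if valid.size == 0:
        logger.debug("no valid segment at lag %d", lag_bins)
        return float("nan"), valid
    return float(valid.mean()), valid


def _per_lag_significance(r_mat: np.ndarray, alpha: float, min_segments: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean r, significance flag and valid-segment count per non-negative lag,
    via a one-sided one-sample t-test on the per-segment r values."""
    if r_mat.shape[0] == 0:
        n_lag = r_mat.shape[1] if r_mat.ndim == 2 else 0
        return (np.full(n_lag, np.nan), np.zeros(n_lag, bool),
                np.zeros(n_lag, int))
    mask = np.isfinite(r_mat)
    nv = mask.sum(axis=0)
    safe_n = np.maximum(nv, 1)
    r0 = np.where(mask, r_mat, 0.0)
    mean_r = np.where(nv > 0, r0.sum(axis=0) / safe_n, np.nan)
    z = np.where(mask, np.arctanh(np.clip(r0, -1 + 1e-12, 1 - 1e-12)), 0.0)
    mean_z = z.sum(axis=0) / safe_n
    var_z = (z * z).sum(axis=0) - safe_n * mean_z * mean_z
    sd_z = np.sqrt(np.maximum(var_z, 0.0) / np.maximum(nv - 1, 1))
    ok = nv >= max(min_segments, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd_z > 0, mean_z / np.where(sd_z > 0, sd_z, 1.0)
                     * np.sqrt(safe_n), np.where(mean_z != 0, np.inf, 0.0))
        # one-sided: only positive correlation indicates transmission
        p = stats.t.sf(t, np.maximum(nv - 1, 1))
    sig = ok & (p < alpha)
    return mean_r, sig, nv


def pair_correlogram(a_binned: np.ndarray, b_binned: np.ndarray,
                     config: ConnectivityConfig | None = None) -> Correlogram:
    """Full +/-max_lag correlogram for an ordered pair.

    Non-negative lags are computed with segments anchored to the source
    train's grid; negative lags reuse the mirrored direction, making the
    correlogram of (b, a) the exact reflection of that of (a, b).
    """
    if config is None:
        config = ConnectivityConfig()
    a = np.asarray(a_binned, dtype=float)
    b = np.asarray(b_binned, dtype=float)
    L = config.max_lag_bins
    seg = config.seg_bins
    r_fwd, _ = _segment_r_matrix(a, b, seg, L)
    r_bwd, _ = _segment_r_matrix(b, a, seg, L)
    mr_f, sig_f, nv_f = _per_lag_significance(r_fwd, config.alpha, config.min_segments)
    mr_b, sig_b, nv_b = _per_lag_significance(r_bwd, config.alpha, config.min_segments)
    if mr_f.size == 0:
        mr_f = np.full(L + 1, np.nan); sig_f = np.zeros(L + 1, bool); nv_f = np.zeros(L + 1, int)
    if mr_b.size == 0:
        mr_b = np.full(L + 1, np.nan); sig_b = np.zeros(L + 1, bool); nv_b = np.zeros(L + 1, int)
    lags = np.arange(-L, L + 1) * config.bin_ms
    r = np.concatenate([mr_b[1:][::-1], mr_f])
    sig = np.concatenate([sig_b[1:][::-1], sig_f])
    nv = np.concatenate([nv_b[1:][::-1], nv_f])
    return Correlogram(lags_ms=lags, r=r, significant=sig, n_segments=nv)


# ---------------------------------------------------------------------------
# peak extraction and filtering


def significant_run_peaks(correlogram: Correlogram,
                          config: ConnectivityConfig | None = None
                          ) -> list[tuple[float, float]]:
    """Candidate peaks of a correlogram.

    Each maximal run of >= ``min_run`` consecutive significant lag bins with
    positive mean r contributes the (lag_ms, r) of its maximum r; a run that
    spans both lag signs contributes one candidate per direction (forward and
    backward transmission superposed across zero lag).  A candidate is kept
    only if its amplitude exceeds the correlogram noise floor by
    ``peak_z`` robust SDs (median/MAD over all lags).
    """
    if config is None:
        config = ConnectivityConfig()
    sig = correlogram.significant
    r = correlogram.r
    lags = correlogram.lags_ms
    finite = r[np.isfinite(r)]
    if finite.size:
        floor = float(np.median(finite))
        noise = float(np.median(np.abs(finite - floor)) * 1.4826)
    else:
        floor, noise = 0.0, 0.0
    peaks: list[tuple[float, float]] = []
    i, n = 0, sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j]:
            j += 1
        if j - i >= config.min_run and np.nanmean(r[i:j]) > 0:
            idx = np.arange(i, j)
            for side in (lags[idx] > 0, lags[idx] < 0, lags[idx] == 0):
                if not side.any():
                    continue
                sub = idx[side]
                k = int(sub[np.nanargmax(r[sub])])
                if r[k] - floor > config.peak_z * max(noise, 1e-12):
                    if lags[k] != 0:
                        peaks.append((float(lags[k]), float(r[k])))
        i = j
    return peaks


def implied_velocity_m_s(distance_um: float, lag_ms: float) -> float:
    return (distance_um * 1e-6) / (abs(lag_ms) * 1e-3)


def velocity_filter(peaks: list[tuple[float, float]], distance_um: float,
                    velocity_range: tuple[float, float] = (0.1, 0.8)
                    ) -> list[tuple[float, float]]:
    """Keep peaks whose implied conduction velocity distance/|lag| lies in
    the admissible range; zero-lag peaks (undefined velocity) are dropped."""
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    lo, hi = velocity_range
    kept = []
    for lag_ms, r in peaks:
        if lag_ms == 0:
            continue
        v = implied_velocity_m_s(distance_um, lag_ms)
        if lo <= v <= hi:
            kept.append((lag_ms, r))
    return kept


# ---------------------------------------------------------------------------
# graph assembly


def build_graph(recording: Recording,
                config: ConnectivityConfig | None = None) -> FunctionalGraph:
    """Run the SCA chain for every unit pair and assemble the functional graph.

    Each unordered pair is evaluated once over the full +/- lag span;
    positive-lag peaks create source->target edges and negative-lag peaks the
    reverse.  Units sharing an electrode (zero distance, undefined velocity)
    are excluded from edge formation.
    """
    if config is None:
        config = ConnectivityConfig()
    g = nx.MultiDiGraph()
    layout = recording.layout
    for tr in recording.trains:
        x, y = layout.position(tr.electrode_id)
        g.add_node(tr.unit_id, electrode_id=tr.electrode_id, x=x, y=y)
    trains = recording.trains
    if len(trains) < 2:
        return FunctionalGraph(directed=g)

    binned = {tr.unit_id: bin_train(tr, config.bin_ms, recording.duration)
              for tr in trains}
    for i in range(len(trains)):
        for j in range(i + 1, len(trains)):
            a, b = trains[i], trains[j]
            dist = layout.distance_um(a.electrode_id, b.electrode_id)
            if dist <= 0:
                continue
            cg = pair_correlogram(binned[a.unit_id], binned[b.unit_id], config)
            peaks = [(lag, r) for lag, r in significant_run_peaks(cg, config)
                     if r >= config.min_weight]
            for lag_ms, r in velocity_filter(peaks, dist, config.velocity_range):
                if lag_ms > 0:
                    g.add_edge(a.unit_id, b.unit_id, lag_ms=lag_ms,
                               weight=float(np.clip(r, 0.0, 1.0)), distance_um=dist)
                else:
                    g.add_edge(b.unit_id, a.unit_id, lag_ms=-lag_ms,
                               weight=float(np.clip(r, 0.0, 1.0)), distance_um=dist)
    return FunctionalGraph(directed=g)


def score_against_truth(graph: FunctionalGraph, truth: TopologyGroundTruth,
                        recording: Recording) -> dict[str, float]:
    """Directed-edge recall and precision of the inferred pair-level graph
    against the planted wiring (edges mapped unit -> electrode)."""
    unit_to_el = {tr.unit_id: tr.electrode_id for tr in recording.trains}
    inferred = {(unit_to_el[u], unit_to_el[v])
                for u, v in graph.pair_directed.edges()
                if unit_to_el[u] != unit_to_el[v]}
    true_edges = set(truth.edges)
    tp = len(inferred & true_edges)
    recall = tp / len(true_edges) if true_edges else float("nan")
    precision = tp / len(inferred) if inferred else float("nan")
    return {"recall": recall, "precision": precision,
            "n_inferred": float(len(inferred)), "n_true": float(len(true_edges))}
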