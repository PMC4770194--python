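"""Topology-constrained spiking-network simulator with known ground truth.

Builds the four engineered-culture topology classes on an MEA layout — linear
chains confined to rows ("2D"), rook-adjacency grids ("4D"), king-adjacency
grids ("8D"), and spatially embedded random graphs — and simulates 5-minute
recordings whose statistical structure matches what the downstream analysis
assumes: recurring network-wide bursts entering the pattern from the edge
columns, spikes propagating along planted edges with distance-derived
conduction delays (velocity drawn from 0.1-0.8 m/s), Gaussian spike-time
jitter, per-edge probabilistic transmission, per-unit refractoriness, and
independent Poisson background firing.

Every run returns the planted :class:`TopologyGroundTruth` so that inferred
functional connectivity can be scored against the true wiring.
"""
from __future__ import annotations

import heapq
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import ElectrodeLayout, Recording, SpikeTrain

__all__ = [
    "ElectrodeLayout",
    "TopologySpec",
    "SimulationConfig",
    "TopologyGroundTruth",
    "build_topology",
    "simulate_recording",
    "write_simulation",
    "make_voltage_trace",
    "TOPOLOGY_KINDS",
]

logger = logging.getLogger(__name__)

TOPOLOGY_KINDS = ("chain2d", "grid4d", "grid8d", "random")


@dataclass(frozen=True)
class TopologySpec:
    """A planted wiring diagram over the electrodes of a layout.

    ``adjacency`` holds ordered (directed) node pairs; the symmetric topology
    classes plant both directions of every structural link.
    """

    kind: str
    layout: ElectrodeLayout
    adjacency: frozenset[tuple[int, int]]
    node_positions: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for u, v in self.adjacency:
            if u == v:
                raise ValueError("adjacency must not contain self-pairs")

    def undirected_edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.adjacency}

    def mean_degree(self) -> float:
        if not self.node_positions:
            return 0.0
        return 2.0 * len(self.undirected_edges()) / len(self.node_positions)


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording.

    Units: times in seconds unless the name says otherwise; rates in Hz;
    ``burst_rate`` in network-burst initiations per minute; jitter/refractory
    in milliseconds; velocities in m/s.
    """

    duration: float = 300.0
    burst_rate: float = 24.0
    spikes_per_burst_mean: float = 15.0
    burst_isi0_ms: float = 10.0
    burst_isi_decay: float = 0.92
    burst_isi_jitter: float = 0.4   # lognormal sigma on source intra-burst ISIs
    burst_window_s: float = 0.5
    burst_unit_cap: int = 12
    edge_burst_cap: int = 4
    p_transmit: float = 0.5
    velocity_range: tuple[float, float] = (0.1, 0.8)
    velocity_sample_range: tuple[float, float] = (0.15, 0.5)
    jitter_sd_ms: float = 1.0
    refractory_ms: float = 3.0
    background_rate: float = 0.2
    units_per_electrode: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_transmit <= 1.0:
            raise ValueError("p_transmit must lie in [0, 1]")
        lo, hi = self.velocity_range
        if not (0 < lo < hi):
            raise ValueError("velocity_range must satisfy 0 < low < high")
        slo, shi = self.velocity_sample_range
        if not (lo <= slo < shi <= hi):
            raise ValueError("velocity_sample_range must lie within velocity_range")
        for name in ("duration", "burst_rate", "background_rate", "jitter_sd_ms",
                     "refractory_ms", "spikes_per_burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.units_per_electrode < 1:
            raise ValueError("units_per_electrode must be >= 1")


@dataclass
class TopologyGroundTruth:
    """The planted truth a simulation was generated from."""

    edges: list[tuple[int, int]]            # directed (src, dst) electrode pairs
    delay_ms: dict[tuple[int, int], float]
    p_transmit: dict[tuple[int, int], float]
    burst_times: list[float]
    burst_sources: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"src": u, "dst": v, "delay_ms": self.delay_ms[(u, v)],
             "p_transmit": self.p_transmit[(u, v)]}
            for u, v in self.edges
        ]
        return pd.DataFrame(rows, columns=["src", "dst", "delay_ms", "p_transmit"])


# ---------------------------------------------------------------------------
# topology construction


def _grid_neighbors(layout: ElectrodeLayout, diagonal: bool) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for r in range(layout.rows):
        for c in range(layout.cols):
            u = r * layout.cols + c
            steps = [(0, 1), (1, 0)]
            if diagonal:
                steps += [(1, 1), (1, -1)]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < layout.rows and 0 <= cc < layout.cols:
                    v = rr * layout.cols + cc
                    pairs.add((u, v))
                    pairs.add((v, u))
    return pairs


def build_topology(
    kind: str,
    layout: ElectrodeLayout | None = None,
    random_params: dict | None = None,
    seed: int = 0,
) -> TopologySpec:
    """Construct a planted topology of one of the four classes.

    ``chain2d`` links each electrode to its within-row predecessor and
    successor (parallel line patterns, one chain per row); ``grid4d`` uses
    rook adjacency; ``grid8d`` king adjacency (diagonal shortcuts);
    ``random`` draws a spatially embedded random graph whose connection
    probability decays exponentially with distance, calibrated so the mean
    degree hits ``random_params['target_mean_degree']`` (default 15).
    """
    if layout is None:
        layout = ElectrodeLayout.grid()
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"unknown topology kind {kind!r}; expected one of {TOPOLOGY_KINDS}")
    if kind in ("grid4d", "grid8d", "chain2d") and (layout.rows * layout.cols
                                                    != layout.n_electrodes):
        raise ValueError(f"{kind} requires a regular grid layout")

    positions = {eid: layout.position(eid) for eid in layout.electrode_ids}

    if kind == "chain2d":
        pairs: set[tuple[int, int]] = set()
        for r in range(layout.rows):
            for c in range(layout.cols - 1):
                u = r * layout.cols + c
                pairs.add((u, u + 1))
                pairs.add((u + 1, u))
    elif kind == "grid4d":
        pairs = _grid_neighbors(layout, diagonal=False)
    elif kind == "grid8d":
        pairs = _grid_neighbors(layout, diagonal=True)
    else:
        params = dict(random_params or {})
        target = float(params.get("target_mean_degree", 15.0))
        decay = float(params.get("decay_um", 1000.0))
        n = layout.n_electrodes
        if target > n - 1:
            raise ValueError(f"target mean degree {target} exceeds n-1 = {n - 1}")
        rng = np.random.default_rng(seed)
        ids = list(layout.electrode_ids)
        xy = np.array([positions[e] for e in ids])
        d = np.hypot(xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1])
        w = np.exp(-d / decay)
        np.fill_diagonal(w, 0.0)
        # calibrate the base probability so the expected mean degree equals target
        p0 = target * n / w.sum()
        p = np.clip(p0 * w, 0.0, 1.0)
        draw = rng.random((n, n))
        pairs = set()
        for i in range(n):
            for j in range(i + 1, n):
                if draw[i, j] < p[i, j]:
                    pairs.add((ids[i], ids[j]))
                    pairs.add((ids[j], ids[i]))

    return TopologySpec(kind=kind, layout=layout, adjacency=frozenset(pairs),
                        node_positions=positions)


# ---------------------------------------------------------------------------
# spike-train simulation


def _edge_column_nodes(layout: ElectrodeLayout) -> list[int]:
    """Burst initiation sites: the first and last column of the grid."""
    if layout.cols >= 2:
        nodes = []
        for r in range(layout.rows):
            nodes.append(r * layout.cols)
            nodes.append(r * layout.cols + layout.cols - 1)
        return sorted(set(nodes))
    return sorted(layout.electrode_ids)


def simulate_recording(
    topology: TopologySpec,
    config: SimulationConfig | None = None,
) -> tuple[Recording, TopologyGroundTruth]:
    """Simulate one recording on a planted topology.

    Network bursts initiate at Poisson times (``burst_rate`` per minute per
    connected pattern) at a random edge-column node of that pattern; the
    source emits a Poisson-count packet of spikes
    with geometrically decaying inter-spike intervals; every accepted spike is
    offered across each outgoing edge and arrives after the edge delay plus
    Gaussian jitter with probability ``p_transmit``, subject to the per-unit
    refractory period.  Bursts terminate by synaptic depletion, modelled at
    two levels: each synapse (directed edge) releases at most
    ``edge_burst_cap`` spikes per burst — keeping postsynaptic arrivals
    sparse and delay-locked even at high in-degree — and each unit fires at
    most ``burst_unit_cap`` spikes per burst, so activity propagates as a
    decaying wave instead of reverberating indefinitely; the burst window is
    a hard safety cap on top.  Background Poisson spikes are
    superposed on every unit and do not propagate.  Fully deterministic given
    ``config.seed``.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    layout = topology.layout
    ids = list(layout.electrode_ids)
    upe = config.units_per_electrode

    if not topology.adjacency and config.background_rate == 0:
        logger.warning("empty adjacency and zero background rate: no activity to simulate")

    # ground truth: one velocity/delay per directed edge; true velocities are
    # drawn interior to the admissible filter band (physiological conduction
    # speeds of unmyelinated cultured axons cluster mid-band)
    lo, hi = config.velocity_sample_range
    edges = sorted(topology.adjacency)
    delay_ms: dict[tuple[int, int], float] = {}
    p_edge: dict[tuple[int, int], float] = {}
    for (u, v) in edges:
        dist_um = math.hypot(
            topology.node_positions[u][0] - topology.node_positions[v][0],
            topology.node_positions[u][1] - topology.node_positions[v][1],
        )
        velocity = rng.uniform(lo, hi)
        delay_ms[(u, v)] = (dist_um * 1e-6) / velocity * 1e3
        p_edge[(u, v)] = config.p_transmit

    out_edges: dict[int, list[tuple[int, int]]] = {e: [] for e in ids}
    for (u, v) in edges:
        out_edges[u].append((u, v))

    # burst initiations: each connected pattern is an independent little
    # network and bursts at the configured rate, entering at one of its own
    # edge-column nodes
    sites = set(_edge_column_nodes(layout))
    parent = {e: e for e in ids}

    def _find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (u, v) in edges:
        ra, rb = _find(u), _find(v)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    components: dict[int, list[int]] = {}
    for e in ids:
        components.setdefault(_find(e), []).append(e)

    events: list[tuple[float, int]] = []
    for root in sorted(components):
        comp_sites = sorted(sites.intersection(components[root]))
        if not comp_sites:
            continue
        n_b = rng.poisson(config.burst_rate * config.duration / 60.0)
        times = rng.uniform(0.0, config.duration, size=n_b)
        chosen = rng.choice(comp_sites, size=n_b)
        events.extend((float(t), int(s)) for t, s in zip(times, chosen))
    events.sort()
    burst_times = [t for t, _ in events]
    burst_sources = [s for _, s in events]

    refr = config.refractory_ms * 1e-3
    jit = config.jitter_sd_ms * 1e-3
    spikes: dict[tuple[int, int], list[float]] = {
        (e, j): [] for e in ids for j in range(upe)
    }
    last: dict[tuple[int, int], float] = {k: -math.inf for k in spikes}

    # event-driven propagation: (time, seq, electrode, deadline, burst index)
    heap: list[tuple[float, int, int, float, int]] = []
    seq = 0
    for bi, (t0, src) in enumerate(zip(burst_times, burst_sources)):
        count = rng.poisson(config.spikes_per_burst_mean)
        t = t0
        isi = config.burst_isi0_ms * 1e-3
        deadline = t0 + config.burst_window_s
        for _ in range(count):
            heapq.heappush(heap, (t, seq, src, deadline, bi))
            seq += 1
            step = isi
            if config.burst_isi_jitter > 0:
                step *= float(np.exp(rng.normal(0.0, config.burst_isi_jitter)))
            t += step
            isi *= config.burst_isi_decay

    fired_in_burst: dict[tuple[int, int, int], int] = {}
    released: dict[tuple[int, int, int], int] = {}
    while heap:
        t, _, node, deadline, bi = heapq.heappop(heap)
        if t > deadline or t >= config.duration:
            continue
        for j in range(upe):
            key = (node, j)
            if t - last[key] < refr:
                continue
            nfired = fired_in_burst.get((node, j, bi), 0)
            if nfired >= config.burst_unit_cap:
                continue   # somatic depletion for this burst
            fired_in_burst[(node, j, bi)] = nfired + 1
            last[key] = t
            spikes[key].append(t)
            for (u, v) in out_edges[node]:
                ek = (u, v, bi)
                if released.get(ek, 0) >= config.edge_burst_cap:
                    continue   # synaptic vesicle depletion for this burst
                if rng.random() < p_edge[(u, v)]:
                    released[ek] = released.get(ek, 0) + 1
                    t_arr = t + delay_ms[(u, v)] * 1e-3
                    if jit > 0:
                        t_arr += rng.normal(0.0, jit)
                    if t_arr > t:   # causality: jitter never moves arrival before emission
                        heapq.heappush(heap, (t_arr, seq, v, deadline, bi))
                        seq += 1

    # background Poisson spikes, superposed, non-propagating
    if config.background_rate > 0:
        for e in ids:
            for j in range(upe):
                n_bg = rng.poisson(config.background_rate * config.duration)
                for t in np.sort(rng.uniform(0.0, config.duration, size=n_bg)):
                    key = (e, j)
                    spikes[key].append(float(t))

    trains = []
    for e in ids:
        for j in range(upe):
            ts = np.array(sorted(spikes[(e, j)]), dtype=float)
            # enforce strict ordering at recording resolution
            if ts.size > 1:
                keep = np.concatenate([[True], np.diff(ts) > 1e-9])
                ts = ts[keep]
            ts = ts[ts < config.duration]
            trains.append(SpikeTrain(unit_id=e * upe + j, electrode_id=e, times=ts))

    rec = Recording(trains=trains, layout=layout, duration=config.duration,
                    metadata={"topology": topology.kind, "seed": config.seed})
    truth = TopologyGroundTruth(edges=edges, delay_ms=delay_ms, p_transmit=p_edge,
                                burst_times=burst_times, burst_sources=burst_sources)
    return rec, truth


# ---------------------------------------------------------------------------
# output files


def write_simulation(rec: Recording, truth: TopologyGroundTruth,
                     config: SimulationConfig, out_dir: str | Path) -> None:
    """Write spike trains, layout, planted edge list and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in rec.trains:
        for t in tr.times:
            rows.append((tr.unit_id, tr.electrode_id, t))
    pd.DataFrame(rows, columns=["unit_id", "electrode_id", "time_s"]).to_csv(
        out / "spikes.csv", index=False, float_format="%.9f")
    lay = rec.layout
    pd.DataFrame({"electrode_id": lay.electrode_ids, "x_um": lay.x, "y_um": lay.y}
                 ).to_csv(out / "layout.csv", index=False)
    truth.to_frame().to_csv(out / "ground_truth_edges.csv", index=False,
                            float_format="%.6f")
    manifest = {"config": asdict(config), "metadata": rec.metadata,
                "n_bursts": len(truth.burst_times)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_voltage_trace(
    spike_times_s: np.ndarray,
    duration: float,
    sampling_rate: float = 25_000.0,
    noise_sd: float = 1.0,
    amplitude: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize a raw extracellular trace: Gaussian noise plus a biphasic
    (negative-leading) spike template at each given time.  Used to exercise
    threshold spike detection; not a biophysical model.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    trace = rng.normal(0.0, noise_sd, size=n)
    # biphasic template spanning ~1.2 ms
    tt = np.arange(int(0.0012 * sampling_rate)) / sampling_rate
    template = -np.sin(2 * np.pi * tt / tt[-1]) * np.exp(-tt / 4e-4)
    template *= amplitude / np.abs(template).max()
    for t in np.asarray(spike_times_s, dtype=float):
        i = int(round(t * sampling_rate))
        j = min(i + template.size, n)
        if i < n:
            trace[i:j] += template[: j - i]
    return trace
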