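import numpy as np
import pytest

from netfidelity._core import ElectrodeLayout, Recording, SpikeTrain
from netfidelity.synthetic_data import (
    SimulationConfig,
    TopologySpec,
    build_topology,
    simulate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid_layout():
    return ElectrodeLayout.grid()


def make_poisson_recording(n_electrodes=12, rate=2.0, duration=300.0, seed=0,
                           rows=3, cols=4):
    """Independent Poisson units on a small grid (no planted edges)."""
    rng = np.random.default_rng(seed)
    lay = ElectrodeLayout.grid(rows=rows, cols=cols)
    trains = []
    for e in lay.electrode_ids[:n_electrodes]:
        n = rng.poisson(rate * duration)
        times = np.unique(rng.uniform(0, duration * 0.999999, n))
        trains.append(SpikeTrain(unit_id=e, electrode_id=e, times=times))
    lay_sub = ElectrodeLayout(
        lay.electrode_ids[:n_electrodes], lay.x[:n_electrodes],
        lay.y[:n_electrodes], rows=rows, cols=cols, pitch=lay.pitch)
    return Recording(trains=trains, layout=lay_sub, duration=duration)


def relay_chain_recording(duration=120.0, p_transmit=1.0, jitter_sd_ms=0.0,
                          background_rate=0.0, seed=3):
    """Directed 3-node relay 0 -> 1 -> 2 on a 1x4 row.

    The fourth electrode is an isolated sink, so burst initiation (first/last
    column) drives only node 0 of the chain and node 3 (which has no outgoing
    edges); trains 1 and 2 are pure relays of train 0.
    """
    lay = ElectrodeLayout.grid(rows=1, cols=4)
    topo = TopologySpec("chain2d", lay, frozenset({(0, 1), (1, 2)}),
                        {e: lay.position(e) for e in lay.electrode_ids})
    cfg = SimulationConfig(duration=duration, p_transmit=p_transmit,
                           jitter_sd_ms=jitter_sd_ms,
                           background_rate=background_rate, seed=seed,
                           edge_burst_cap=10**6)
    return simulate_recording(topo, cfg), cfg


@pytest.fixture(scope="session")
def grid4d_session():
    """One default grid4d simulation shared by read-only tests."""
    topo = build_topology("grid4d")
    cfg = SimulationConfig(duration=300.0, seed=1)
    rec, truth = simulate_recording(topo, cfg)
    return topo, cfg, rec, truth
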