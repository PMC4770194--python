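import numpy as np
import pytest

from netfidelity._core import ElectrodeLayout, Recording, SpikeTrain
from netfidelity.functional_connectivity import (
    ConnectivityConfig,
    Correlogram,
    bin_train,
    build_graph,
    pair_correlogram,
    scaled_correlation,
    significant_run_peaks,
    velocity_filter,
)

from conftest import relay_chain_recording


class TestBinTrain:
    def test_half_open_bins(self):
        train = SpikeTrain(0, 0, np.array([0.0005, 0.0015]))
        counts = bin_train(train, 1.0, 0.01)
        assert counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_empty_train(self):
        assert bin_train(np.array([]), 1.0, 0.005).tolist() == [0] * 5

    def test_count_conservation(self, rng):
        for _ in range(100):
            t = np.unique(rng.uniform(0, 0.999, rng.integers(1, 200)))
            assert bin_train(t, 1.0, 1.0).sum() == t.size


class TestScaledCorrelation:
    def _cfg(self):
        return ConnectivityConfig()

    def test_self_correlation_is_one(self, rng):
        t = np.unique(rng.uniform(0, 30, 500))
        binned = bin_train(t, 1.0, 30.0)
        r, segs = scaled_correlation(binned, binned, self._cfg(), 0)
        assert r == pytest.approx(1.0)
        assert np.allclose(segs, 1.0)

    def test_shifted_copy_peaks_at_shift(self, rng):
        t = np.unique(rng.uniform(0.1, 29.0, 400))
        a = bin_train(t, 1.0, 30.0)
        b = np.roll(a, 5)
        r, _ = scaled_correlation(a, b, self._cfg(), 5)
        assert r == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        """Mean scaled correlation of independent 2 Hz Poisson trains stays
        within +/-0.05 of zero across 100 draws."""
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = bin_train(np.unique(rng.uniform(0, 300, 600)), 1.0, 300.0)
            b = bin_train(np.unique(rng.uniform(0, 300, 600)), 1.0, 300.0)
            r, _ = scaled_correlation(a, b, self._cfg(), int(rng.integers(-50, 51)))
            if np.isfinite(r):
                vals.append(r)
        assert abs(np.mean(vals)) < 0.05

    def test_direction_antisymmetry(self, rng):
        """r_ab(+tau) equals r_ba(-tau) exactly, by construction."""
        a = bin_train(np.unique(rng.uniform(0, 30, 300)), 1.0, 30.0)
        b = bin_train(np.unique(rng.uniform(0, 30, 300)), 1.0, 30.0)
        cfg = self._cfg()
        for lag in (1, 7, 23):
            r_fwd, _ = scaled_correlation(a, b, cfg, lag)
            r_bwd, _ = scaled_correlation(b, a, cfg, -lag)
            assert r_fwd == pytest.approx(r_bwd, nan_ok=True)

    def test_no_valid_segment_flagged(self):
        cfg = self._cfg()
        a = np.zeros(4000, dtype=int)
        b = np.zeros(4000, dtype=int)
        r, segs = scaled_correlation(a, b, cfg, 0)
        assert np.isnan(r) and segs.size == 0

    def test_mirrored_correlogram(self, rng):
        a = bin_train(np.unique(rng.uniform(0, 30, 300)), 1.0, 30.0)
        b = bin_train(np.unique(rng.uniform(0, 30, 250)), 1.0, 30.0)
        cfg = self._cfg()
        ab = pair_correlogram(a, b, cfg)
        ba = pair_correlogram(b, a, cfg)
        np.testing.assert_allclose(ab.r, ba.r[::-1], equal_nan=True)


class TestRunPeaks:
    def _corr(self, sig_lags, r_by_lag, L=100):
        lags = np.arange(-L, L + 1, dtype=float)
        r = np.zeros(lags.size)
        sig = np.zeros(lags.size, dtype=bool)
        for lag, val in r_by_lag.items():
            r[lag + L] = val
        for lag in sig_lags:
            sig[lag + L] = True
        return Correlogram(lags, r, sig, np.full(lags.size, 50))

    def test_isolated_bin_no_peak(self):
        cg = self._corr([4], {4: 0.5})
        assert significant_run_peaks(cg) == []

    def test_run_of_three_yields_peak(self):
        cg = self._corr([3, 4, 5], {3: 0.2, 4: 0.5, 5: 0.3})
        peaks = significant_run_peaks(cg)
        assert peaks == [(4.0, 0.5)]

    def test_run_spanning_zero_yields_both_directions(self):
        cg = self._corr([-2, -1, 0, 1, 2], {-2: 0.3, -1: 0.4, 0: 0.45,
                                            1: 0.5, 2: 0.35})
        peaks = sorted(significant_run_peaks(cg))
        assert peaks == [(-1.0, 0.4), (1.0, 0.5)]

    def test_all_zero_correlogram_no_peaks(self):
        cg = self._corr([], {})
        assert significant_run_peaks(cg) == []

    def test_negative_mean_run_rejected(self):
        cg = self._corr([3, 4, 5], {3: -0.2, 4: -0.5, 5: -0.3})
        assert significant_run_peaks(cg) == []


class TestVelocityFilter:
    def test_printed_arithmetic(self):
        """500 um at 1 ms is 0.5 m/s (kept); 0.5 ms and 10 ms imply 1.0 and
        0.05 m/s (discarded)."""
        peaks = [(1.0, 0.5), (0.5, 0.6), (10.0, 0.4)]
        kept = velocity_filter(peaks, 500.0)
        assert kept == [(1.0, 0.5)]

    def test_zero_lag_discarded(self):
        assert velocity_filter([(0.0, 0.9)], 500.0) == []

    def test_negative_lags_use_magnitude(self):
        assert velocity_filter([(-1.0, 0.5)], 500.0) == [(-1.0, 0.5)]

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            velocity_filter([(1.0, 0.5)], 0.0)


class TestBuildGraph:
    def test_single_unit_empty_graph(self):
        lay = ElectrodeLayout.grid(rows=1, cols=2)
        rec = Recording([SpikeTrain(0, 0, np.arange(1.0, 50.0))], lay, 60.0)
        g = build_graph(rec)
        assert g.directed.number_of_edges() == 0
        assert g.directed.number_of_nodes() == 1

    def test_reciprocal_pair_average_weight(self):
        import networkx as nx
        from netfidelity.functional_connectivity import FunctionalGraph
        d = nx.MultiDiGraph()
        d.add_node(0, x=0.0, y=0.0)
        d.add_node(1, x=500.0, y=0.0)
        d.add_edge(0, 1, lag_ms=1.0, weight=0.4, distance_um=500.0)
        d.add_edge(1, 0, lag_ms=2.0, weight=0.6, distance_um=500.0)
        g = FunctionalGraph(directed=d)
        assert g.undirected[0][1]["weight"] == pytest.approx(0.5)
        assert g.undirected[0][1]["reciprocal"]

    def test_noise_free_chain_recovered_with_direction(self):
        """Deterministic transmission with no background: the planted chain
        edges are recovered with the correct direction.  Physiological
        spike-time jitter is kept — with none, all correlation mass falls in
        at most two 1 ms lag bins and no 3-bin run can form."""
        (rec, truth), _ = relay_chain_recording(duration=300.0, seed=8,
                                                jitter_sd_ms=1.0)
        g = build_graph(rec)
        inferred = set(g.pair_directed.edges())
        assert {(0, 1), (1, 2)} <= inferred

    def test_same_electrode_units_excluded(self):
        lay = ElectrodeLayout.grid(rows=1, cols=2)
        rng = np.random.default_rng(0)
        t = np.unique(rng.uniform(0, 60, 300))
        trains = [SpikeTrain(0, 0, t), SpikeTrain(1, 0, t + 1e-4)]
        rec = Recording(trains, lay, 60.0)
        g = build_graph(rec)
        assert g.directed.number_of_edges() == 0
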