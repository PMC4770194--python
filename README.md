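# netfidelity

Structure-function analysis of engineered neuronal networks on
microelectrode arrays (MEAs): from spike trains to burst statistics,
scaled-cross-correlation functional connectivity, Victor-Purpura
transmission fidelity, and graph-theoretic network characterization —
together with a spiking-network simulator that plants known wiring so every
stage of the analysis can be validated against ground truth.

## The scientific problem

Cortical neurons cultured over a 60-electrode MEA (6 x 10 grid, 500 um
pitch) can be grown into engineered topologies — parallel lines ("2D"),
rook-adjacency grids ("4D"), king-adjacency grids with diagonal shortcuts
("8D"), or left to wire themselves ("Random"). The question this package
serves: how does that wiring — a node's degree, the path length between
neurons, local clustering — shape the *fidelity* with which one neuron's
spike train is reproduced in another's?

Three quantitative tools carry the analysis:

- **Burstlets** (Wagenaar rule): runs of >= 4 spikes with inter-spike
  intervals below 25% of the unit's mean ISI; burst duration is reported as
  3 x SD of the qualifying ISIs (< 10 ms discarded), peak rate from a
  5 ms-smoothed 1 ms-bin histogram.
- **Scaled cross-correlation (SCA)**: Pearson correlations of 1 ms-binned
  spike counts inside 20 ms quasi-stationary segments, averaged per lag
  over +/-100 ms — robust to burst-induced non-stationarity.  A directed
  connection requires three consecutive significant lag bins, a peak
  standing clear of the correlogram noise floor, and an implied conduction
  velocity (distance/lag) inside 0.1-0.8 m/s.  Connections are weighted by
  the peak Pearson r; reciprocal pairs collapse to an average-weighted
  undirected link.
- **Victor-Purpura fidelity**: the distance D between two spike trains is
  the minimal cost of editing one into the other (insert/delete cost 1,
  shift cost q per unit time).  Normalized, D_v = D/(n1+n2) in [0, 1], and
  fidelity is lambda = 1 - D_v.  Sweeping the cost scale 1/q probes rate
  coding (80-200 ms) versus precise spike timing (2-20 ms).

Functional graphs are then characterized with degree (in/out/total),
characteristic path length, clustering (binary and weighted), betweenness,
closeness, local efficiency, assortativity, density, and reciprocal
connection statistics; group contrasts use Welch t-tests with Mann-Whitney
U alongside and Benjamini-Hochberg control.

No recordings of this kind are publicly deposited, so the package ships a
first-class simulator (`netfidelity.synthetic_data`) that builds the four
topology classes on the MEA layout and generates 5-minute recordings with
network bursts entering from the pattern edges, per-edge conduction delays
(0.15-0.5 m/s), 1 ms synaptic jitter, probabilistic transmission, synaptic
depletion, refractoriness and Poisson background — returning the planted
wiring so recall and precision of the inference are measurable.
See `docs/methods.md` for the full model description and known limits.

## Worked example

```python
import netfidelity as nf

topo = nf.build_topology("grid4d")                 # rook grid on 6x10 MEA
cfg = nf.SimulationConfig(duration=300.0, seed=1)
rec, truth = nf.simulate_recording(topo, cfg)      # recording + ground truth
graph = nf.build_graph(rec)                        # SCA edge inference
print(nf.score_against_truth(graph, truth, rec))
```

prints

```
{'recall': 0.9326923076923077, 'precision': 0.8434782608695652, 'n_inferred': 230.0, 'n_true': 208.0}
```

i.e. 93% of the 208 planted directed connections are recovered, and 84% of
inferred edges are real — the residual false positives are mostly two-step
relays whose summed delay still implies a plausible conduction velocity.

Fidelity across cost scales, for a spike train relayed with 5 ms jitter
(`examples/transmission_fidelity.py`):

```
5 ms jitter:
  1/q =     2 ms   lambda = 0.288
  1/q =    20 ms   lambda = 0.900
  1/q =   200 ms   lambda = 0.990
  rate-band mean 0.983   temporal-band mean 0.650
```

Jitter barely touches rate-scale similarity but erodes fine temporal
structure — the signature the band summaries are designed to separate.

The `examples/` directory holds one short script per capability
(simulation, burst statistics, connectivity inference, fidelity sweeps,
and the full four-topology study).

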