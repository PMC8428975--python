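# gliasim

Simulation and statistical analysis of spatial neuron–astrocyte networks
under healthy and pathology-inspired parameter regimes.

Astrocytes are not passive support cells: at the *tripartite synapse* they
take up synaptic glutamate, respond with IP₃-mediated Ca²⁺ transients, and
feed signals back to the synapse — depressing it via ATP/P2X-receptor
signalling and potentiating it via gliotransmitter release.  Several
hypotheses link schizophrenia to disturbances of exactly these elements:
reduced astrocyte and neuron densities, amplified astrocytic ATP
signalling, altered glutamate release/uptake, and shifted synaptic weights.
`gliasim` provides a tested pipeline to explore those hypotheses *in
silico*: it builds MEA-like spatial networks, simulates their coupled
spiking/calcium dynamics, extracts spike, burst and astrocyte-activation
features, and quantifies parameter effects with linear mixed-effects (LME)
models.

## Model in brief

Neurons are stochastic rate units on a 5 ms grid.  Neuron *i* fires with
probability 1 − e^(−λᵢ), where

    λᵢ(t_k) = max(0, cᵢ + Σⱼ y_ij·s_j(t_{k−1}) − Σⱼ y_Astro·A_ija(t_{k−1}))

with noise cᵢ, synaptic weights y_ij, spike indicators s_j, and the flag
A_ija marking synapses whose enclosing astrocyte is active (each
contributing the depression y_Astro).  Excitatory synapses carry a slow
glutamate pool that shapes the effective weight; astrocytes convert the
phasic glutamate they take up into mGluR occupancy Γ, IP₃ and calcium,

    [Ca²⁺](t_k) = [Ca²⁺](t_{k−1}) + Ω_acc·([IP₃](t_k) − [Ca²⁺](t_{k−1})),

and, when Ca²⁺ crosses a threshold, activate: they release stored
glutamate (potentiating their synapses) and depress them for the duration
of the activation window.  Three response variables summarise a run: mean
spike rate (spikes/min), mean burst rate (bursts/min, cumulative-moving-
average burst detector on the ISI histogram), and mean activations per
astrocyte.  Full equations, parameters and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from gliasim import (ConnectivityParams, SimulationParams, place_cells,
                     connect_network, run_simulation, response_record,
                     topology_metrics)

npos, apos = place_cells(250, 107, seed=1)      # MEA-like 750x750 um slab
net = connect_network(npos, apos, ConnectivityParams(), seed=2)
print(topology_metrics(net))
trace = run_simulation(net, SimulationParams(seed=500))   # 5 simulated min
print(response_record(trace))
```

prints (numbers from this exact seed pair):

```
TopologyMetrics(connectivity_pct=27.261..., avg_gap_junctions=4.392..., exc_without_astro_pct=10.126...)
{'Z_spike': 188.98, 'Z_burst': 22.53, 'Z_astro': 27.48}
```

i.e. 27.3 % of ordered neuron pairs are connected, each astrocyte has on
average 4.4 gap-junction neighbours, and the healthy network fires at
189 spikes/min — inside the 30–200 spikes/min range of healthy MEA
cultures — with 22.5 bursts/min per neuron and 27.5 activations per
astrocyte in 5 minutes.

The numbered scripts under `analysis/` run the full study at desk scale:

```bash
python analysis/01_build_networks.py    # nine networks + topology metrics
python analysis/02_healthy_baseline.py  # healthy responses + glutamate trace
python analysis/03_h1_removal.py        # 25 % astro/neuron removal + LME
python analysis/04_h2_atp.py            # y_Astro sweep + log-scale LME
python analysis/05_h3_glutamate.py      # (w_f, w_g) grid + response surface
python analysis/06_h4_weights.py        # weight-bound grid + response surface
```

Each writes tidy CSVs under `results/` (`responses_*.csv`,
`table_*.csv`, `surface_*.csv`).  The same functionality is exposed as a
CLI (`gliasim suite|h1|h2|h3|h4|analyze|reproduce`); `gliasim reproduce
--scale desk` runs everything end to end and writes a checksummed manifest.

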