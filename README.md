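# megnet

Resting-state MEG network analysis linking physical fitness, brain network
topology, and intelligence. The package implements the full analysis chain
for sensor-level magnetoencephalography: band-limited functional
connectivity by the phase lag index, weighted-network modularity found by
simulated annealing, node-role metrics under the resulting partition,
covariate-adjusted group statistics with per-sensor FDR correction, and
bootstrap mediation analysis — together with synthetic-data generators that
plant known structure at every stage, so the whole pipeline can be
validated against ground truth.

## The analysis

**Connectivity.** For two channels with instantaneous phases φ₁(t), φ₂(t)
(analytic-signal phase of the band-filtered epoch), the phase lag index is

    PLI = | ⟨ sign( sin(Δφ(t_k)) ) ⟩ |,  Δφ = φ₁ − φ₂ ∈ [−π, π].

A consistent non-zero phase lead/lag gives PLI → 1; zero-lag coupling — the
signature of volume conduction and common sources at the sensor level —
contributes nothing. Per subject and band (delta 0.5–4, theta 4–8, lower
alpha 8–10, upper alpha 10–13, beta 13–30, gamma 30–45 Hz), PLI matrices
from five 4096-sample epochs (6.554 s at 625 Hz) are averaged.

**Modularity.** For a partition of the weighted network into modules s,

    Q = Σ_s [ l_s/L − (d_s/2L)² ],

with l_s the within-module link weight, d_s the module's summed node
strength, and L the total link weight. The maximum-Q partition is searched
by simulated annealing with cost C = −Q: one random node is relabelled per
step, worsening moves are accepted with probability exp(−ΔC/T), and T
starts at 1 and shrinks by ×0.995 every 100 steps over 10⁶ steps (the
schedule is configurable; an exhaustive set-partition oracle is available
for N ≤ 10). Under the best partition each node gets a within-module degree
z-score Zᵢ, a participation coefficient PC = 1 − Σ_m (κ_im/kᵢ)², and a
between-module connectivity (mean weight to out-module nodes).

**Group statistics.** Per-band regressions of modularity on VO₂ max
adjusted for sex, head surface, and band relative power; per-sensor
association maps with Benjamini–Hochberg FDR at q < 0.05; and mediation of
the VO₂ max → IQ association through network topology, with a 5,000-sample
case-resampling bootstrap CI for the indirect effect a·b.

## Worked example

Plant two 4-channel modules with phase-lagged upper-alpha coupling, compute
the epoch-averaged PLI network, and recover the structure:

```python
import numpy as np
from megnet import (OscillatorSpec, generate_coupled_oscillators, pli_matrix,
                    BandDefinition, anneal_partition, AnnealingConfig,
                    node_roles, average_epochs, mean_connectivity)

spec = OscillatorSpec(
    n_channels=8, module_labels=(0, 0, 0, 0, 1, 1, 1, 1),
    carrier_band=(10.0, 13.0), coupling_within=0.9, coupling_between=0.1,
    noise_sd=0.5, n_epochs=5, seed=42,
)
epochs = generate_coupled_oscillators(spec)
band = BandDefinition("upper_alpha", 10.0, 13.0)
avg = average_epochs([pli_matrix(ep, band) for ep in epochs])
print("mean PLI:", round(mean_connectivity(avg), 3))
part = anneal_partition(avg, AnnealingConfig(total_steps=100_000, seed=0))
print("Q:", round(part.q, 3), "modules:", part.n_modules)
print("labels:", part.labels)
print("pc:", np.round(node_roles(avg, part).pc, 3))
```

prints

```
mean PLI: 0.512
Q: 0.329 modules: 2
labels: [0 0 0 0 1 1 1 1]
pc: [0.27  0.289 0.29  0.283 0.291 0.3   0.276 0.269]
```

The annealer recovers exactly the planted two-module split; Q = 0.329
reflects the moderate between-module leakage (coupling_between = 0.1), and
every node's participation coefficient is well below the 0.5 bound of a
two-module network, i.e. all nodes are predominantly intramodular.

A full synthetic study (per-subject signals, covariates, config) can be
generated and analysed from the shell:

```
megnet synth study_dir --n-subjects 30 --seed 1
megnet study --config study_dir/config.yaml
```

which writes per-band regression, sensor-map, and mediation tables under
`study_dir/results/`.

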