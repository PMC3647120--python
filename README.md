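# shuntnet

Dendritic shunting-inhibition modelling toolkit: a hierarchy of neuron
models — from a three-compartment conductance neuron, through reduced
single-compartment models with a multiplicative excitation × inhibition
shunting rule, to a spiking excitatory/inhibitory network in which
peri-somatic inhibition acts as a global shunting gate — plus the
mean-field fixed-point and stability analysis that explains the network's
low-rate persistent activity.

## Modules

| module | contents |
| --- | --- |
| `shuntnet.compartmental` | exact 3-compartment steady state + ODE integration, empirical shunting-strength (κ) extraction, distance-dependent transfer conductances, κ-vs-distance scans |
| `shuntnet.reduced` | closed-form somatic response functions and κ for five synaptic geometries (on-path, out-of-path, single-per-branch, paired-on-path, global shunting), reduced-neuron simulation, multiplicative-decomposition identity |
| `shuntnet.synapses` | spike-driven exponential conductances, seeded Poisson spike trains |
| `shuntnet.network` | recurrent spiking E/I network with global shunting gates, fixed in-degree wiring, raster/rate analysis |
| `shuntnet.meanfield` | linearized response functions, fixed-point rates, closed-form + numeric eigenvalue stability, rate sweeps |
| `shuntnet.config` / `shuntnet.cli` | flat-YAML configuration, experiment runners, provenance dumps |

## CLI

```bash
shuntnet response-curves  --out results/curves
shuntnet kappa-scan       --out results/kappa
shuntnet kappa-distance   --out results/kappa_distance
shuntnet simulate-neuron  --out results/neuron  --seed 1 --duration 500
shuntnet simulate-network --out results/net     --seed 1 --duration 500
shuntnet meanfield        --out results/mf      --sweep w_E:20:26:0.5
```

All subcommands accept `--config FILE` (flat YAML; unknown keys rejected)
and write delimited text tables plus a `resolved_params.yaml` provenance
dump. Exit codes: 0 success, 2 configuration error, 3 numerical failure.

Example configuration override:

```yaml
# cfg.yaml — smaller network, stronger recurrence
N_E: 1000
N_I: 250
w_E: 26
```

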