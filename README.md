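# dynsort

Spike sorting of electrically evoked neural activity on dense
multi-electrode arrays (MEAs), in the presence of the stimulation artifact,
using linear dynamical-systems models and windowed input estimation.

## The problem

Bi-directional neural interfaces stimulate neurons and record the evoked
responses on the same electrode array. The injected current produces an
artifact that lasts up to ~2 ms, overlaps the 0.4–0.6 ms spike latency of
retinal ganglion cells, and can saturate the stimulating electrode —
masking exactly the spikes one needs to build *activation curves* (spiking
probability vs stimulus current) and extract 50% activation thresholds.
`dynsort` solves this by modeling the distinct spatiotemporal propagation
of spikes and artifact:

* per neuron, a state-space model `x[t+1] = A_n x[t] + B_n u_n[t]`,
  `y_n[t] = C_n x[t]` over the neuron's relevant electrodes, driven by a
  two-pulse input template `r_n` so that the template-driven simulation
  reproduces the neuron's electrical image (EI);
* one artifact model of the same form on the electrodes around the
  stimulating electrode (the stimulating electrode itself is excluded),
  driven by a three-pulse template scaled by the stimulus amplitude `q`;
* an aggregate model whose output is the superposition
  `y[t] = Σ_n y_n[t] + y_a[t] + w[t]`;
* an input estimator that inverts the aggregate over a forward window
  `y[t..t+L]`, treating the artifact input as known and ignoring corrupted
  electrodes, to recover which input templates — hence which spikes —
  produced the measurements: `(û[t], x̂[t]) = f(y[t..t+L], x̂[t−1], u_a[t], I)`.

Detected spikes are aggregated into activation curves; a logistic fit in
log amplitude yields the 50% threshold per neuron–electrode pair. All
components are validated end-to-end on a synthetic MEA generator with known
ground truth (geometry, EIs, artifact, Bernoulli activation).

## Worked example

Run the end-to-end synthetic demo (simulate a 4-neuron 8×8 preparation,
fit EI and artifact models, sort every trial, fit the target neuron's
activation curve):

```bash
dynsort run --seed 3 --out demo
```

prints

```
seed: 3
stim_electrode: 18
mean_ei_snrmse: 0.13695789291194546
sorting_accuracy: 1.0
target_q50_true_uA: 1.2
target_q50_recovered_uA: 1.1837116269436212
sigmoid_converged: True
```

meaning: the fitted EI models reproduce their electrical images to ~14%
normalized RMS error on this deliberately small array (neurons whose
footprints run off an 8×8 grid fit worst; on the 16×16 validation arrays
the mean is 2–4%); every one of the 130 trials gets exactly the correct
set of detected neurons; and the recovered 50% activation threshold of the
target neuron (1.184 µA) matches the simulated ground truth (1.2 µA) to
1.4%. `demo/` contains the spike calls (`calls.csv`), ground truth and a
`summary.json`.

The same stages are available as individual subcommands
(`dynsort simulate | fit-ei | fit-artifact | sort | activation | kfold |
compare`) operating on HDF5/CSV files, and as a Python API:

```python
from dynsort import (build_grid_geometry, fit_all_eis, PipelineConfig,
                     assemble, sort_recording)
```

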