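# neurochar

Systematic characterization of neuron and ion-channel models: spike-train
electrophysiology, variable-timestep computational complexity, nested
clustering of cell-model behavior, voltage-clamp scoring and clustering of
channel models, and normalized channel densities linking the two scales.

## Who this is for

Computational neuroscientists who maintain or mine collections of spiking
models (NeuroML-style cell models, NMODL-style channels, abstract point
neurons) and want uniform, automated answers to: *how does this model
spike, how expensive is it to simulate, which other models behave like it,
and which channel complements underlie each behavioral group?*

All stages run end to end on a built-in synthetic-data generator with
known ground truth, so every algorithm in the package is testable without
a model database or a neural simulator.

## The methods

**Electrophysiology (42 properties).** From square current injections at
1.5× and 3.0× rheobase (1 s pulse after a 1 s delay), 19 action-potential
and spike-train properties per stimulus level — delays, AP shape
(amplitude, half-width, AHP), ISI statistics, and accommodation measures —
giving 38 core properties, plus four more: resting AP count, time to first
spike under a 1 rheobase/s ramp, and the two inflection frequencies of a
bi-sigmoidal "hat" curve fitted to AP counts across 29–143 Hz triple-pulse
trains. Rheobase is found by bracketed bisection (1% relative tolerance);
intrinsically spiking models are flagged non-positive-rheobase instead.

**Computational complexity.** Variable-step integrators spend a baseline
number of steps per simulated second plus extra steps per action
potential, so total steps are fitted as
`steps = steps_base + steps_ap · APs` by OLS over a 13-current series
(0 nA, the largest known sub-rheobase current, and 11 evenly spaced
currents on [rheobase, 1.5·rheobase]). Absolute complexity at a 10 Hz
target rate is `Ω_abs = (steps_base + steps_ap·10) · runtime_step`, and
`Ω_HH = Ω_abs / Ω_abs(reference)` expresses it in reference (HH) units —
the reference model is 1 HH by definition.

**Nested cell clustering.** Features are filled (per-feature min/max/mean
policies), compressed with the bi-symmetric log
`y = sgn(x)·log10(1 + |x|/C)`, z-scored, and reduced by PCA keeping 95% of
variance. HDBSCAN (minimum cluster size 10) gives the first two cluster
levels, recursing into the largest cluster with the PCA refit on the
subset; the third level is K-means with the cluster count chosen by
silhouette score over k = 2–10. Density "noise" points are assigned to the
nearest cluster center, so every model receives a label.

**Channel scoring and clustering.** Voltage-clamp responses (activation /
deactivation / inactivation protocols) are condensed to fixed-length
vectors, a probabilistic PCA keeping 99% of variance is learned per
protocol over the channel population, and every channel model is scored by
its log-likelihood under each protocol's model — a 3-vector per channel.
Family score matrices are reduced by a second PCA (99%) and clustered with
Ward-linkage agglomerative clustering under an adaptive dendrogram cut
that allows singleton clusters.

**Normalized channel densities (NCD).** Somatic conductance densities are
parsed from NeuroML-subset documents into a cells × channels matrix in
mS/cm² (absent channel → 0), each column is scaled by its maximum across
cells, and scaled densities are summed over each discovered channel
cluster. Per-cell-cluster means carry percentile-bootstrap 95% confidence
intervals.

## Worked example

```bash
neurochar run -c examples/demo_config.yaml -o demo_out
```

runs every stage on a 120-model synthetic population (seed 7) and prints
per-stage artifacts. `demo_out/complexity.csv` then holds, per model, the
fitted step model and its complexity:

```
           steps_base  steps_ap  fit_r2  omega_abs_s  omega_hh
cell_0000    2676.266   184.141   0.998        0.045     1.000
cell_0001    1248.677   322.045   0.999        0.045     0.989
cell_0002     536.280   135.662   0.998        0.019     0.419
```

`cell_0000` is the reference, so its `omega_hh` is exactly 1; `cell_0002`
needs about 0.42 of the reference's wall-clock time to simulate one
second at 10 Hz. `demo_out/report.json` summarizes the run:

```json
{
 "cell_clusters": {"final_leaves": 2, "level1": 2},
 "channel_clusters": {"n_subtypes": 6},
 "complexity": {"n_models": 120, "omega_hh_max": 2.11, "omega_hh_min": 0.42}
}
```

i.e. the nested analysis found two behavioral clusters at the top level,
the 24 channel models fell into 6 kinetic sub-types, and simulated costs
span 0.42–2.11 HH. `demo_out/ncd_summary.csv` gives the average NCD of
each channel sub-type within each cell cluster with bootstrap 95% CIs.

The same stages are available individually (`neurochar synth`,
`neurochar features`, …) and as library functions (`neurochar.ephys`,
`neurochar.complexity`, `neurochar.cellcluster`, `neurochar.chancluster`,
`neurochar.ncd`).

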