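# Methods

This note documents the models and procedures implemented in `neurochar`,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where more than one reasonable
implementation existed.

## Stimulus protocols

Current-clamp waveforms follow the standard characterization set: square
(1 s pulse after a 1 s delay by default), long square, ramp (current
`slope · rheobase · t` for `t` seconds after onset; the default feature
uses 1 rheobase/s), pink noise (1/f spectral shaping of seeded white
noise, scaled to a target RMS), short square (3 ms pulse by default — the
published protocol sets do not restate the width, so it is configurable),
and short-square triples whose pulse onsets are spaced `1000/f` ms.
Units are ms / nA / mV throughout; stimulus windows are half-open.

The complexity benchmark series is 0 nA, the largest known sub-rheobase
current, and 11 evenly spaced currents spanning `[rheobase,
1.5·rheobase]` inclusive — 13 amplitudes. A non-positive rheobase makes
the benchmark inapplicable (intrinsically spiking model) and is an error.

## Spike detection and rheobase

Spikes are upward crossings of a voltage threshold (default 0 mV) with
events closer than a 1 ms refractory window merged. Traces that *rest* at
or above the threshold — abstract point models often rest at 0 mV — fall
back to a derivative criterion (default dV/dt ≥ 20 mV/ms).

Rheobase search brackets the threshold by doubling a probe current
(start 0.05 nA, maximum 10 nA by default) and bisects to 1% relative
tolerance (≤ 30 iterations). The lower bracket at termination is recorded
as the largest known sub-rheobase current and feeds the benchmark series.
Spiking at 0 nA short-circuits the search with a non-positive-rheobase
flag; never spiking up to the maximum raises.

## The 42 features

The canonical supplement defining the 38 core action-potential/spike-train
properties is not restated in the characterization literature we follow,
so this package defines 19 per-response properties measured at both 1.5×
and 3.0× rheobase (38 total): delay to first and second AP; amplitude,
half-width and AHP depth of the first two APs and their percent changes;
AP count and mean rate; mean/median ISI and ISI CV; initial accommodation
(2nd vs 1st ISI), steady-state accommodation (mean ISI in the last
quarter of the stimulus vs the first ISI, percent), and a per-ISI
multiplicative drift from a log-linear ISI fit. The four added properties
are the resting AP count, the time to the first ramp-evoked spike, and
the two inflection frequencies of a bi-sigmoid
`base + amp·σ((f−f_lo)/s_lo)·σ((f_hi−f)/s_hi)` fitted to AP counts at
eight log-spaced triple-pulse frequencies on [29, 143] Hz. Any property
that cannot be measured (too few spikes, failed fit, non-positive
rheobase) is NaN — missing, never silently zero.

## Feature preparation

The order is fill → bi-symmetric log → z-score, and it matters (the
transform of a z-score is not a z-score). Filling uses per-feature
policies (min / max / cross-model mean; default mean) supplied as
configuration; an entirely missing column is an error rather than a
guess. The bi-symmetric log is `sgn(x)·log10(1 + |x|/C)` with
`C = 1/ln 10` so the transform has unit slope at the origin; it is odd,
smooth, and total on the reals. By default every feature is transformed;
a column subset can be configured. Z-scoring maps zero-variance columns
to 0 with a warning.

## Nested cell clustering

Level 1: PCA retaining 95% of variance (smallest such component count),
HDBSCAN with minimum cluster size 10 on the scores, density noise
reassigned to the nearest cluster's geometric center (arithmetic mean of
member scores; ties break to the lowest cluster index). Level 2 repeats
this inside the largest level-1 cluster — by default; an override selects
the cluster — with the **PCA refit on the subset**. Level 3 runs K-means
(seeded, 10 restarts) for k = 2..10 inside the largest level-2 cluster
and keeps the k with the highest mean silhouette. Recursion stops early
at any level that yields fewer than two clusters or a subset too small to
cluster. Every model receives a final leaf label.

Refitting the PCA per level is essential, not cosmetic: directions that
carry a sub-cluster split often hold so little global variance that the
95% threshold discards them at the parent level; they dominate the
variance only within the subset. The level-2/3 refit is done on the raw
(already globally standardized) subset rows *without re-z-scoring inside
the subset* — re-standardizing would rescale exactly the low-variance
directions the recursion needs to see at their natural scale.

## Channel condensation, scoring, clustering

Voltage-clamp protocols (activation: steps −80..+50 mV from a −80 mV
hold; deactivation: steps −120..0 mV after a +40 mV activating pulse;
inactivation: −100..+20 mV prepulse then a +40 mV test) are simulated for
first-order gating `g = m·h` with sigmoidal steady states and constant
time constants, solved in closed form per voltage segment.

Condensation resamples each step's current trace onto a fixed grid
(default 512 points/step; tests use smaller grids), concatenates steps,
and normalizes each model's row by its maximum absolute current so the
representation carries kinetics rather than amplitude.

Scoring fits a probabilistic PCA retaining 99% of variance per protocol
and evaluates each model's marginal log-likelihood under each protocol's
model — a 3-vector per channel. The PPCA is fitted on the **pooled
channel population** (all families) and each family's models are scored
under it; fitting per family is also supported but is degenerate when the
family decomposes into balanced sub-groups: the 99% PCA then retains
exactly the between-group directions and whitens every balanced group to
the same Mahalanobis radius, making the likelihoods indistinguishable.
Against the pooled reference, sub-groups sit at distinct distances and
separate. Real model populations are also unbalanced, which further
differentiates group likelihoods; the synthetic archetype generator
mirrors this (default sizes 15/9/6).

The family score matrix is reduced by a second PCA (99%) and clustered
with Ward linkage. The dendrogram is cut top-down by an adaptive rule:
a merge is severed when its height exceeds twice the larger internal
height of its subtrees (`gap_ratio = 2`) and is at least 5% of the root
height (`height_floor_frac = 0.05`). Leaves count as height zero, so an
isolated model can fall out as a singleton cluster; homogeneous data
yield a single cluster. This is this package's interpretation of an
adaptive ("dynamic") tree cut — parameters are exposed and recorded.

## Normalized channel densities

The parser reads NeuroML-subset documents and keeps `channelDensity`
elements whose segment group resolves to the soma (group name containing
"soma" by default, configurable; a missing group attribute means
"everywhere", which includes the soma). Units are converted to mS/cm²
(`S_per_cm2`, `mS_per_cm2`, `S_per_m2`, `mS_per_m2` accepted). A channel
absent from a document is exactly 0. Multiple somatic entries for one
channel are averaged area-unweighted — segment areas are not part of the
parsed subset; an area-weighted mean is the natural alternative if they
become available.

Each channel column is scaled by its maximum across cells (all-zero
columns stay zero), which preserves between-cell correlation structure,
and scaled densities are summed per discovered channel cluster into the
NCD matrix. Summaries are cluster means with percentile-bootstrap 95%
confidence intervals (default 10,000 resamples of cells with replacement,
seeded). A |Z| < 3 outlier mask is provided for visualization only;
summaries always use all models.

## Computational complexity

`fit_step_model` is plain OLS of total steps on AP counts over all 13
benchmark rows, unweighted; a negative slope is clamped to zero with a
warning, identical AP counts everywhere are an error. `runtime_step` —
mean wall-clock seconds per integration step — is a *measured input*
(the convention is a fixed-step quiet-machine run), not something this
package computes, so results are hardware-independent until that one
number is supplied. The target rate defaults to 10 APs/s and is
overridable; the HH-relative ratio cancels `runtime_step` whenever both
models share one measurement.

## The synthetic-data generator

Spiking neurons are phenomenological: spike times are computed in closed
form (first spike at `onset + delay/strength`, ISIs
`isi_base/strength · rate^k`, with `strength = amp/(1.5·rheobase)` — a
documented monotone rule), and stylized AP waveforms (instantaneous
rise, linear decay over two half-widths, AHP) are inserted into a
low-pass-filtered passive response. Ground truth is therefore exact:
delay and ISIs are recoverable to one sample, amplitude and half-width to
one sample/1%. Optional Gaussian trace noise and an optional triple-pulse
frequency pass-band are part of the spec. What this does **not** emulate:
conductance-based AP shape diversity, channel noise, adaptation currents,
stochastic firing, or any interaction between AP shape and firing rate —
so passing recovery tests demonstrates the *extractors* are correct, not
that the generator spans real electrophysiology.

Step-count tables are exactly linear without noise and Poisson-distributed
around the linear mean with it. Channel responses use the same first-order
gating as the scoring stage (they share assumptions; the clustering tests
are therefore within-model-class checks). Conductance documents are
NeuroML-subset XML with log-normal densities (median 5 mS/cm², log-sd 1,
80% presence), mixed units to exercise the parser, and genuinely absent
channels.

The planted 4→2→6 hierarchy places each level's structure in its own
feature block at a decreasing scale (within-cluster sds 1, 0.2, 0.012;
centers separated by `separation` × the level's sd), makes the recursed
branch tight in its parent's dimensions, gives the sibling branch an
anisotropic spread so the subset PCA keeps two components, and
size-balances sub-cluster offsets so no sub-level structure leaks into
parent-level means. This is precisely the regime in which
variance-thresholded PCA hides sub-structure at the parent level and the
per-level refit reveals it — the mechanism the nested analysis relies on.

## Numerical choices and degenerate inputs

- PCA uses the full SVD solver; "95%/99%" means the smallest component
  count whose cumulative explained variance reaches the threshold.
- K-means is seeded with 10 restarts; all-identical rows are an error.
- HDBSCAN runs with library defaults beyond the minimum cluster size; a
  sample with no detectable density structure is returned as one cluster
  rather than all-noise.
- The hat-curve fit is bounded (`scipy.optimize.curve_fit`) and returns
  NaN inflections for flat count profiles or failed fits.
- Bisection tolerances, detection thresholds, fill policies, and cut
  parameters are all exposed as function arguments or pipeline
  configuration and echoed into the run manifest.

## Pipeline and reproducibility

`run_pipeline` executes synth → features → complexity → cluster-cells →
cluster-channels → ncd → report against one output directory, validates
the YAML/JSON configuration against a schema, refuses to run a stage
whose upstream artifact is missing, and writes a JSON manifest (config
snapshot, seed, stage timings, SHA-256 of every artifact). All randomness
descends from the config seed; a rerun reproduces byte-identical tables.
The demo uses 120 synthetic cells and 24 channel models (two families),
sizes chosen so a full run stays in the tens of seconds on one core while
leaving each stage with enough data to find structure.

## Known limitations

- The 19×2 property set is this package's reconstruction of the standard
  38-property characterization; names and formulas are documented here
  rather than inherited from the original supplement.
- The steady-state accommodation window (last 25% of the stimulus) is an
  interpretation; alternatives (exponential ISI fits) would shift values
  but not orderings.
- Channel-model clustering quality depends on the population used to fit
  the per-protocol PPCA; a family scored against an unrepresentative
  pool can collapse distinct kinetics onto one likelihood level.
- The NeuroML parser reads the channel-density subset only — no
  morphology, no per-segment areas, no Nernst-style densities.
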