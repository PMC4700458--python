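# cardiowave

Analysis of action-potential (AP) variability in optically mapped cardiac
cell clusters.

Early-stage stem-cell-derived cardiomyocyte preparations are
electrophysiologically heterogeneous: a single beating cluster can contain
cells with short triangular APs next to cells with long plateau APs.
High-resolution voltage-dye imaging records hundreds of AP waveforms per
cluster (one per camera pixel), and the question becomes how to quantify
that variability and divide the recorded APs into putative phenotype
groups.  `cardiowave` implements that analysis end to end, together with a
ground-truthed simulator of optical-mapping movies so every stage can be
validated against planted truth.

## What it computes

**Per-site AP parameters.** Each recording site is reduced to one
ensemble-averaged, amplitude-normalized AP (beats aligned at the
activation time t_act, the instant of fastest upstroke) and quantified by

- APD30, APD80 — AP duration from t_act to 30% / 80% repolarization,
- triangulation = APD80 − APD30,
- fractional repolarization = (APD80 − APD30) / APD80,

with level crossings linearly interpolated between samples.  Rate
dependence is summarized per site by the least-squares slope of APD80 and
of fractional repolarization against pacing rate.

**Grouping strategies.** Over a pooled AP population:

1. *APD80 threshold* — a two-component Gaussian mixture fitted to the
   APD80 distribution, split at the density crossover;
2. *PCA threshold* — the first principal component of (APD30, APD80),
   split at a two-Gaussian crossover of the scores;
3. *Waveform spectral clustering* — pairwise similarity
   S_ij = exp(−CSE_ij / 2σ²), where CSE is the cumulative squared error
   between whole waveforms, clustered via the symmetric normalized graph
   Laplacian into k = 2 or 3 groups.

Strategies are compared by the Davies-Bouldin index (in √CSE distance;
lower = tighter, better-separated groups), by SVM-derived linear
boundaries in parameter planes with the percentage of APs on the wrong
side, and by Levene's test of equal variances.

**Simulator.** Parametric AP templates (logistic upstroke × delayed
logistic repolarization) are tuned by a root-finding solver so their
*measured* APD30/APD80 hit requested targets; clusters are laid out as
spatially connected phenotype regions; movies add optical blur, baseline
drift, and Gaussian noise at a default 100×100 px, 500 fps geometry.

## Worked example

```python
import numpy as np
from cardiowave import synthetic as syn, pipeline, grouping

# one cluster, two AP phenotypes in separate halves
layout = syn.split_layout(syn.elliptical_mask(24, 24), 2)
templates = [syn.preset_template("short_triangular"),   # APD30/APD80 = 50/100 ms
             syn.preset_template("long_plateau")]       # APD30/APD80 = 150/220 ms
schedule = syn.PacingSchedule(mode="paced", rates=(90.0,), record_duration=8.0)
acq = syn.AcquisitionConfig(height=24, width=24, noise_sd=0.05)
movie, truth = syn.generate_cluster_movie(layout, templates, schedule, acq, seed=1)

pre, table = pipeline.analyze_movie(movie, cluster_id="demo", pacing_rate_bpm=90.0)
print(table[["apd30_ms", "apd80_ms", "triangulation_ms",
             "fractional_repolarization"]].describe().round(1))

sim = grouping.waveform_similarity(pre.aps[table["site_index"]])
labels = grouping.spectral_cluster(sim, k=2, seed=0)
print("DBI (waveform, k=2):",
      round(grouping.davies_bouldin(pre.aps[table["site_index"]], labels), 3))
```

prints

```
       apd30_ms  apd80_ms  triangulation_ms  fractional_repolarization
count     276.0     276.0             276.0                      276.0
mean       95.4     167.0              71.6                        0.5
std        44.5      53.2              20.2                        0.1
min        49.3      99.0              49.0                        0.3
25%        50.4     101.6              51.3                        0.3
50%        78.4     191.8              70.1                        0.5
75%       148.7     219.2              86.8                        0.5
max       150.5     222.1             115.1                        0.6
DBI (waveform, k=2): 0.278
```

The 276 in-mask sites split into the two planted morphologies: the
quartiles sit near the planted (50, 100) and (150, 220) ms targets, with
intermediate values at the region border where spatial filtering mixes
the two signals.  Spectral clustering of the waveforms recovers the
planted phenotype map exactly (adjusted Rand index 1.0 against truth).

A full multi-cluster run — simulation, preprocessing, metrics, all
grouping strategies, and report figures (histograms, iso-contour
parameter maps at 10 ms / 0.05 spacing, group maps, pairwise scatter
with SVM boundaries) — is one command:

```
cardiowave run --seed 0 --out runs/benchmark
```

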