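# Methods

## Signal model and conditioning

A recording is a fluorescence movie F(t, y, x) at fixed frame rate with a
boolean region-of-interest mask tracing the cell cluster.  Optical
voltage signals are relative: no millivolt calibration is attempted, and
all AP metrics are defined on amplitude-normalized waveforms.

Conditioning proceeds per movie:

1. **Spatial boxcar filter.** Every frame is convolved with a normalized
   5×5 uniform kernel (odd sizes only).  Edge handling is replicate
   padding, chosen so cluster borders are not artificially darkened; for
   interior pixels the filter is the exact neighborhood mean.  The mask
   is applied after filtering and is treated as an input (equivalent to a
   manually traced border).
2. **Per-site normalization.** Each in-mask pixel trace is multiplied by
   the polarity (−1 for dyes that report depolarization as a fluorescence
   decrease), a robust straight baseline is subtracted, and the result is
   scaled to baseline 0 / peak 1.  The baseline is fitted by iteratively
   re-weighted least squares restricted to low-residual (diastolic)
   samples (3 iterations, residual quantile 0.3).  Every step is
   affine-equivariant, which makes the operation idempotent to machine
   precision.  The linear baseline stands in for slow photobleaching; it
   is not a model of any specific optical artifact.
3. **Activation detection.** Beats are upward crossings of 0.5 normalized
   amplitude under a refractory lockout (bootstrapped at 100 ms, then
   40% of the median inter-beat interval).  Within each beat, t_act is
   the time of maximum first difference, refined to sub-frame precision
   by quadratic interpolation of the three derivative samples around the
   peak.  Detection is exactly translation-equivariant.
4. **Beat averaging.** Beats are resampled by linear interpolation onto a
   common grid spanning (−50, +600) ms around t_act — wide enough to
   cover the longest phenotype in the library (APD80 257 ms) with margin
   — averaged pointwise, and re-normalized.  Beats whose window runs past
   the record are dropped.  The window is fixed per run because the
   whole-waveform similarity requires identical time support; in
   rate-dependence sweeps the post-activation window shrinks to 85% of
   the cycle length so consecutive beats stay out of it.
5. **Beating-pattern classification.** A spontaneous recording is
   *episodic* when any gap between successive activations reaches 4 s;
   gaps to the record edges do not count (the criterion is about
   quiescence *between* APs).  With fewer than two beats the pattern is
   undetermined.  Rate stability is defined as a coefficient of variation
   of inter-beat intervals ≤ 0.1 — the cutoff is arbitrary but explicit
   and testable.

## AP parameters

APD at fraction r is the time from t_act to the first post-peak crossing
of (1 − r) × amplitude, linearly interpolated between samples; amplitude
is peak minus baseline of the averaged AP.  Taking the *first* crossing
guards against slow repolarizing tails re-crossing the level.
Triangulation is APD80 − APD30 (APD80 rather than a deeper level, for
the same tail reason) and fractional repolarization is
triangulation / APD80.  Durations are measured from t_act rather than
from the peak; the difference is bounded by the upstroke duration
(a few ms at these kinetics).

Rate dependence is the least-squares slope over pacing rates, classified
positive/negative with a flat guard band (|slope| < 0.05 ms/bpm for
APD80, < 2.5×10⁻⁴ /bpm for fractional repolarization) so that noise
around zero slope is not forced into a sign.

## Grouping

- **Two-Gaussian crossover.** Full-covariance two-component mixture via
  EM (10 seeded restarts, tolerance 1e−8).  The threshold is the point
  strictly between the component means where the weighted densities are
  equal — a root of a quadratic in x, selected between the means.
  Degenerate fits (component weight < 1e−3, collapsing variance) raise
  rather than silently thresholding.
- **PCA.** Eigendecomposition of the 2×2 covariance of mean-centered
  (APD30, APD80).  Covariance, not correlation: both variables are in
  ms, so standardization is unnecessary.  Sign convention: APD80 loading
  positive, falling back to APD30 positive when the APD80 loading is
  exactly zero; the equal-eigenvalue tie resolves to (1, 1)/√2.
- **Waveform similarity.** CSE_ij = Σ_t (AP_i − AP_j)²;
  S_ij = exp(−CSE_ij / 2σ²) with σ = median nonzero pairwise √CSE.  The
  median makes the kernel scale-adaptive with one interpretable tunable.
- **Spectral clustering.** Symmetric normalized Laplacian
  I − D^(−1/2) S D^(−1/2); rows of the k leading eigenvectors are
  row-normalized and clustered by k-means (20 seeded restarts).  A
  disconnected similarity graph with exactly k components short-circuits
  to the component partition (warned).  On small populations the
  partition is checked in tests against exhaustive minimum-normalized-cut
  search.
- **Davies-Bouldin index.** Scatter = mean √CSE of members to the group
  mean waveform; separation = √CSE between group mean waveforms;
  DBI = mean over groups of the worst (s_i + s_j)/d_ij.  √CSE (a metric)
  keeps the ratio dimensionally consistent.
- **SVM boundaries.** Linear soft-margin SVM (C = 1) on standardized
  coordinates, boundary mapped back to raw units; the overlap is the
  percentage of APs on the wrong side.  C is fixed for reproducibility,
  not tuned.
- **Levene's test** on absolute deviations from group means (the
  mean-centered variant), via `scipy.stats.levene`.

Grouping runs on the pooled population across clusters; labels are then
mapped back per cluster for spatial display.  k is not selected
automatically: DBI is reported for k ∈ {2, 3} and the choice is left to
the analyst.

## Synthetic data: what it emulates and what it does not

The generator plants known phenotypes so recovery is measurable.  An AP
template is amplitude × logistic(t/τ_up) × logistic(−(t − plateau)/τ_rep):
the minimal phenomenological form whose APD30, APD80, and triangulation
are independently controllable.  When targets are requested, a
coordinate root-finding solver (Brent; τ_rep controls triangulation
nearly independently, plateau then shifts APD30) adjusts the parameters
until the *measured* APDs — measured by the same level-crossing oracle
the analysis uses — hit the targets within 0.5 ms (contract: 2 ms, one
frame at 500 fps; sub-frame precision in targets would be meaningless).
The template peak falls slightly below the nominal amplitude when
upstroke and decay overlap; metrics are amplitude-normalized, so this is
harmless.

The preset library spans the observed phenotype ranges (APD30 46–188 ms,
APD80 85–257 ms, triangulation up to 117 ms, fractional repolarization
0.27–0.51).  Layouts partition an elliptical mask into spatially
connected bands or a blob — echoing the observation that phenotypes
occupy separate areas — without reproducing any particular cluster's
geometry.  Acquisition defaults are 100×100 px at 16 µm pitch and
500 fps, 16 s records, pacing from 60 bpm in 30-bpm steps; noise is
i.i.d. Gaussian per pixel per frame (default 2% of amplitude), optical
blur is a Gaussian kernel (default 1 px), and baseline drift is linear
(default 0.5%/s).  The camera's true noise and blur figures are unknown;
these defaults are plausible placeholders, and recovery criteria are
additionally evaluated at 5% noise.

Deliberately not modeled: ionic-current biophysics, motion artifacts
(acquisition assumed mechanically uncoupled), conduction delays
(activation is near-synchronous across a cluster), shot noise,
nonlinear photobleaching.  Passing recovery tests therefore shows the
pipeline is correct under additive-Gaussian, drift-contaminated,
spatially blurred conditions — not that it is robust to motion or
propagation artifacts.

## Ground-truth evaluation at interior sites

The 5×5 boxcar and optical blur mix signals within ~2–3 px of phenotype
borders; a border pixel's waveform is genuinely a mixture and has no
single planted truth.  Recovery criteria (parameter error, rate-slope
sign) are therefore evaluated at *interior* sites — pixels whose whole
filtering neighborhood lies in one region (`synthetic.interior_mask`,
radius 2 for the boxcar plus ~2σ of blur).  Whole-population criteria
(ARI of grouping) use all sites.

## Determinism and problem sizes

All randomness descends from one integer seed via `numpy` SeedSequence
spawning (independent substreams for event jitter and noise); repeated
runs are bit-identical, and the test suite asserts byte-identical output
tables.  The default benchmark uses 8 clusters of 24×24 px (~280
recording sites each, ~2200 pooled APs) paced at 90 bpm for 8 s — large
enough for stable mixture fits and spectral embeddings while keeping a
full pipeline run around a minute on one core.  Tests use the same or
smaller geometries.

## Known limitations

- The similarity kernel and spectral formulation are one standard choice
  among several; the DBI ordering of grouping methods is stable under
  kernel-scale changes in our tests, but absolute DBI values depend on σ.
- Dense eigendecomposition limits pooled spectral clustering to a few
  thousand waveforms; larger populations need subsampling or sparse
  nearest-neighbor similarity graphs.
- The spontaneous-rate model (jittered periodic, burst-episodic) is
  stylized; it exercises the beating-pattern classifier but does not
  reproduce real pacemaker dynamics.
- Threshold grouping supports k = 2 only (a single crossover); only the
  waveform route produces k = 3.
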