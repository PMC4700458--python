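"""Ground-truthed synthetic optical-mapping movies.

Generates fluorescence movies of cardiac cell clusters containing one or
more action-potential phenotypes, with known per-pixel phenotype labels,
so every downstream stage (conditioning, metric extraction, grouping) can
be validated against planted truth.

The AP template is a phenomenological product of a logistic upstroke and
a delayed logistic repolarization.  Its plateau duration and
repolarization time constant are independently tunable, and a small
solver adjusts them so the *measured* APD30/APD80 of the generated
waveform hit requested targets — the targets, not the raw parameters, are
the scientific ground truth.

Acquisition defaults emulate a 100 x 100 pixel sensor (16 um/pixel)
recording at 500 frames per second for 16-32 s; pacing defaults start at
60 bpm and increment in 30-bpm steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize, special

from .metrics import apd_from_waveform
from .preprocess import Movie

__all__ = [
    "APTemplate",
    "ClusterLayout",
    "PacingSchedule",
    "AcquisitionConfig",
    "SyntheticTruth",
    "ConstraintError",
    "CaptureFailureError",
    "generate_ap_waveform",
    "resolve_template",
    "measure_template",
    "generate_event_times",
    "generate_cluster_movie",
    "elliptical_mask",
    "split_layout",
    "blob_layout",
    "interior_mask",
    "PRESET_TARGETS",
    "preset_template",
]


class ConstraintError(ValueError):
    """Raised for infeasible template targets (e.g. APD30 >= APD80)."""


class CaptureFailureError(ValueError):
    """Pacing rate too fast for 1:1 capture given the AP support."""


@dataclass
class APTemplate:
    """Parametric AP waveform: logistic upstroke x delayed logistic decay.

    v(t) = amplitude / (1 + exp(-(t - t0)/tau_up)) / (1 + exp((t - t0 - plateau)/tau_rep))

    with t0 = 5 * upstroke_time_constant so the waveform starts at
    baseline.  Optional target_apd30/target_apd80 (ms) declare the
    phenotype's intended measured durations; ``resolve_template`` tunes
    plateau_duration and repolarization_time_constant to meet them
    within 2 ms (one frame at 500 fps).
    """

    upstroke_time_constant: float = 2.0  # ms
    plateau_duration: float = 150.0  # ms
    repolarization_time_constant: float = 25.0  # ms
    amplitude: float = 1.0  # arbitrary fluorescence units
    target_apd30: float | None = None
    target_apd80: float | None = None

    def __post_init__(self) -> None:
        if min(self.upstroke_time_constant, self.plateau_duration,
               self.repolarization_time_constant) <= 0:
            raise ConstraintError("all time constants must be positive")
        if self.amplitude <= 0:
            raise ConstraintError("amplitude must be positive")
        if self.target_apd30 is not None and self.target_apd80 is not None:
            if not 0 < self.target_apd30 < self.target_apd80:
                raise ConstraintError("need 0 < target_apd30 < target_apd80")

    @property
    def onset_ms(self) -> float:
        return 5.0 * self.upstroke_time_constant

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the template at arbitrary times (ms, 0 = waveform start)."""
        t = np.asarray(t_ms, dtype=float)
        up = special.expit((t - self.onset_ms) / self.upstroke_time_constant)
        down = special.expit(
            -(t - self.onset_ms - self.plateau_duration) / self.repolarization_time_constant
        )
        return self.amplitude * up * down


@dataclass
class ClusterLayout:
    """Spatial layout of phenotypes in one cluster.

    ``region_labels`` assigns every in-mask pixel a phenotype index
    (contiguous from 0); out-of-mask pixels carry -1.  Regions produced
    by the layout helpers are spatially connected, mirroring the
    observation that distinct phenotypes tend to occupy separate areas
    of a cluster rather than intermingling.
    """

    mask: np.ndarray
    region_labels: np.ndarray
    cluster_id: str = "cluster0"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.region_labels.shape != self.mask.shape:
            raise ValueError("region_labels and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        labels = np.unique(self.region_labels[self.mask])
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValueError("phenotype indices must be contiguous from 0")
        if np.any(self.region_labels[~self.mask] != -1):
            raise ValueError("out-of-mask pixels must be labeled -1")

    @property
    def n_phenotypes(self) -> int:
        return int(self.region_labels[self.mask].max()) + 1


@dataclass
class PacingSchedule:
    """Beat-timing protocol for one recording.

    paced: strictly periodic at ``rates[0]`` bpm (protocols step from
    60 bpm in 30-bpm increments by convention).  spontaneous_continuous:
    near-periodic with optional interval jitter.  spontaneous_episodic:
    bursts separated by quiescent gaps of ``episodic_gap`` >= 4 s.
    """

    mode: str = "paced"
    rates: tuple[float, ...] = (90.0,)
    record_duration: float = 16.0  # s
    episodic_gap: float = 5.0  # s
    burst_beats: int = 4
    jitter_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("paced", "spontaneous_continuous", "spontaneous_episodic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.rates or any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        if self.mode == "spontaneous_episodic" and self.episodic_gap < 4.0:
            raise ValueError("episodic_gap must be >= 4 s (quiescence criterion)")
        if self.record_duration <= 0:
            raise ValueError("record_duration must be positive")


@dataclass
class AcquisitionConfig:
    """Camera and noise model. Defaults emulate the mapping hardware:
    100 x 100 pixels at 16 um pitch, 500 fps."""

    frame_rate: float = 500.0  # frames / s
    height: int = 100
    width: int = 100
    pixel_pitch: float = 16.0  # um
    noise_sd: float = 0.02  # fraction of AP amplitude, i.i.d. Gaussian
    blur_kernel_sd: float = 1.0  # pixels, Gaussian optical blur
    baseline_drift_rate: float = 0.005  # fraction of amplitude per second
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a movie bit-exactly and score
    recovery: per-pixel phenotype labels, the resolved templates, the
    pacing schedule, the acquisition settings, and the seed."""

    region_labels: np.ndarray
    templates: list[APTemplate]
    schedule: PacingSchedule
    acquisition: AcquisitionConfig
    seed: int
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# waveform generation and target solving

_SOLVER_FS = 2000.0  # Hz; solver measures APDs on a finer grid than the camera


def measure_template(template: APTemplate, fs: float = _SOLVER_FS) -> tuple[float, float]:
    """Measured (APD30, APD80) of a template via the metric oracle.

    The waveform is sampled at ``fs``, the activation index taken at the
    maximum first difference, and the standard level-crossing APDs
    computed.  This closes the loop: planted targets are defined in terms
    of the same measurement the analysis applies.
    """
    dt = 1000.0 / fs
    horizon = template.onset_ms + template.plateau_duration + \
        12.0 * template.repolarization_time_constant + 100.0
    t = np.arange(0.0, horizon, dt)
    v = template.evaluate(t)
    j = int(np.argmax(np.diff(v)))
    t_act_index = j + 0.5
    apd30 = apd_from_waveform(v, dt, t_act_index, 0.30, baseline=0.0)
    apd80 = apd_from_waveform(v, dt, t_act_index, 0.80, baseline=0.0)
    return apd30, apd80


def resolve_template(template: APTemplate, tol_ms: float = 0.5) -> APTemplate:
    """Tune plateau_duration and repolarization_time_constant so the
    measured APD30/APD80 hit the template's targets.

    Alternates two 1-D root-finding passes (Brent): the repolarization
    time constant controls triangulation (APD80 - APD30) almost
    independently of the plateau, and the plateau then shifts APD30.
    Converges in a few rounds; the result is guaranteed within ``tol_ms``
    of both targets (well inside the 2 ms = one-frame contract).
    """
    if template.target_apd30 is None or template.target_apd80 is None:
        return template
    a30, a80 = template.target_apd30, template.target_apd80
    if not 0 < a30 < a80:
        raise ConstraintError("need 0 < target_apd30 < target_apd80")
    tri_target = a80 - a30
    # logistic-decay closed form: APD80-APD30 ~ (ln 4 - ln(3/7)) * tau
    tau = tri_target / 2.2336
    plateau = max(1.0, a30 + 0.8473 * tau)
    cur = replace(template, plateau_duration=plateau, repolarization_time_constant=tau)

    def tri_err(tau_try: float, base: APTemplate) -> float:
        m30, m80 = measure_template(replace(base, repolarization_time_constant=tau_try))
        return (m80 - m30) - tri_target

    def apd30_err(plateau_try: float, base: APTemplate) -> float:
        m30, _ = measure_template(replace(base, plateau_duration=plateau_try))
        return m30 - a30

    for _ in range(8):
        tau = optimize.brentq(tri_err, 0.05, 500.0, args=(cur,), xtol=1e-3)
        cur = replace(cur, repolarization_time_constant=tau)
        lo = 0.05
        hi = a30 + 5.0 * tau + 50.0
        plateau = optimize.brentq(apd30_err, lo, hi, args=(cur,), xtol=1e-3)
        cur = replace(cur, plateau_duration=plateau)
        m30, m80 = measure_template(cur)
        if abs(m30 - a30) <= tol_ms and abs(m80 - a80) <= tol_ms:
            return cur
    raise ConstraintError(
        f"could not meet targets APD30={a30}, APD80={a80} "
        f"(reached {m30:.2f}, {m80:.2f})"
    )


def generate_ap_waveform(
    template: APTemplate, duration_ms: float, frame_rate: float
) -> np.ndarray:
    """Sample one AP of the (resolved) template at the camera frame rate.

    The record must exceed the expected APD80 by at least 100 ms so the
    repolarization is resolved.
    """
    resolved = resolve_template(template)
    expected_apd80 = resolved.target_apd80
    if expected_apd80 is None:
        _, expected_apd80 = measure_template(resolved)
    if duration_ms < expected_apd80 + resolved.onset_ms + 100.0:
        raise ValueError("duration must exceed expected APD80 by >= 100 ms")
    dt = 1000.0 / frame_rate
    t = np.arange(0.0, duration_ms, dt)
    return resolved.evaluate(t)


# ---------------------------------------------------------------------------
# event timing

def generate_event_times(
    schedule: PacingSchedule,
    seed: int | np.random.SeedSequence = 0,
    rate_bpm: float | None = None,
    min_support_ms: float = 150.0,
) -> np.ndarray:
    """Activation times (s) for one recording under the given schedule.

    paced: strictly periodic at 60/rate s spacing from t = 0.
    spontaneous_continuous: periodic with multiplicative interval jitter.
    spontaneous_episodic: bursts of ``burst_beats`` beats separated by
    ``episodic_gap`` s of quiescence.  Deterministic given the seed.

    Raises CaptureFailureError when the inter-beat interval is shorter
    than ``min_support_ms`` (loss of 1:1 capture).
    """
    rng = np.random.default_rng(seed)
    rate = float(rate_bpm if rate_bpm is not None else schedule.rates[0])
    period = 60.0 / rate
    if period * 1000.0 < min_support_ms:
        raise CaptureFailureError(
            f"{rate:g} bpm gives {period * 1000:.0f} ms interval < {min_support_ms:g} ms support"
        )
    dur = schedule.record_duration
    if schedule.mode == "paced":
        return np.arange(0.0, dur, period)
    if schedule.mode == "spontaneous_continuous":
        n = int(np.ceil(dur / period)) + 2
        intervals = period * (1.0 + schedule.jitter_cv * rng.standard_normal(n))
        intervals = np.clip(intervals, min_support_ms / 1000.0, None)
        times = np.concatenate([[0.2], 0.2 + np.cumsum(intervals)])
        return times[times < dur]
    # episodic: bursts until the record ends
    times = []
    t = 0.2
    while t < dur:
        for b in range(schedule.burst_beats):
            tb = t + b * period
            if tb < dur:
                times.append(tb)
        t = t + (schedule.burst_beats - 1) * period + schedule.episodic_gap
    return np.asarray(times)


# ---------------------------------------------------------------------------
# geometry helpers

def elliptical_mask(height: int, width: int, margin: int = 2) -> np.ndarray:
    """Elliptical ROI inscribed in the frame with a blank border."""
    r = np.arange(height)[:, None] - (height - 1) / 2.0
    c = np.arange(width)[None, :] - (width - 1) / 2.0
    a = (height - 1) / 2.0 - margin
    b = (width - 1) / 2.0 - margin
    if a <= 0 or b <= 0:
        raise ValueError("frame too small for the requested margin")
    return (r / a) ** 2 + (c / b) ** 2 <= 1.0


def split_layout(mask: np.ndarray, n_regions: int = 2, axis: int = 1,
                 cluster_id: str = "cluster0") -> ClusterLayout:
    """Partition a mask into ``n_regions`` parallel bands of roughly equal
    pixel count (half-plane split for 2).  Bands of a convex mask are
    spatially connected."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.nonzero(mask)[axis]
    edges = np.quantile(coords, np.linspace(0, 1, n_regions + 1)[1:-1]) if n_regions > 1 else []
    pos = np.arange(mask.shape[axis])
    band = np.digitize(pos, edges, right=True)
    labels = np.full(mask.shape, -1, dtype=int)
    grid = band[:, None] * np.ones(mask.shape[1 - axis], dtype=int)[None, :]
    if axis == 1:
        grid = grid.T
    labels[mask] = grid[mask]
    # re-index in case a band got no pixels
    present = np.unique(labels[mask])
    remap = {old: new for new, old in enumerate(present)}
    labels[mask] = np.vectorize(remap.get)(labels[mask])
    return ClusterLayout(mask=mask, region_labels=labels, cluster_id=cluster_id)


def blob_layout(mask: np.ndarray, center: tuple[float, float] | None = None,
                radius: float | None = None, cluster_id: str = "cluster0") -> ClusterLayout:
    """Two-phenotype layout: a circular blob (label 1) inside the mask,
    background label 0."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if radius is None:
        radius = min(h, w) / 5.0
    rr = np.arange(h)[:, None] - center[0]
    cc = np.arange(w)[None, :] - center[1]
    blob = (rr**2 + cc**2) <= radius**2
    labels = np.full(mask.shape, -1, dtype=int)
    labels[mask] = 0
    labels[mask & blob] = 1
    if not (mask & blob).any():
        raise ValueError("blob does not intersect the mask")
    return ClusterLayout(mask=mask, region_labels=labels, cluster_id=cluster_id)


# ---------------------------------------------------------------------------
# movie synthesis

def generate_cluster_movie(
    layout: ClusterLayout,
    templates: list[APTemplate],
    schedule: PacingSchedule,
    acquisition: AcquisitionConfig,
    seed: int = 0,
    rate_bpm: float | None = None,
) -> tuple[Movie, SyntheticTruth]:
    """Render a movie of one cluster and return it with its ground truth.

    Every in-mask pixel carries the AP train of its phenotype; the signal
    field is blurred spatially (Gaussian, ``blur_kernel_sd`` pixels), a
    linear baseline drift is added inside the mask, and i.i.d. Gaussian
    noise of ``noise_sd`` (fractions of mean template amplitude) covers
    the whole frame.  Polarity -1 inverts the recorded signal, emulating
    dyes that report depolarization as a fluorescence decrease.

    One seed fans out to independent substreams for event jitter and
    noise, and the same inputs regenerate the movie bit-exactly.
    """
    if layout.n_phenotypes > len(templates):
        raise ValueError("a template is required for every phenotype in the layout")
    ss = np.random.SeedSequence(seed)
    events_ss, noise_ss = ss.spawn(2)
    events = generate_event_times(schedule, seed=events_ss, rate_bpm=rate_bpm)
    if events.size == 0:
        raise ValueError("schedule produced no beats")

    resolved = [resolve_template(tp) for tp in templates[: max(layout.n_phenotypes, 1)]]
    n_frames = int(round(schedule.record_duration * acquisition.frame_rate))
    t_ms = np.arange(n_frames) * 1000.0 / acquisition.frame_rate

    traces = np.zeros((len(resolved), n_frames))
    for p, tp in enumerate(resolved):
        for e in events:
            traces[p] += tp.evaluate(t_ms - e * 1000.0)

    frames = np.zeros((n_frames, *layout.mask.shape))
    for p in range(layout.n_phenotypes):
        sel = layout.region_labels == p
        frames[:, sel] = traces[p][:, None]
    if acquisition.blur_kernel_sd > 0:
        frames = ndimage.gaussian_filter(
            frames, sigma=(0.0, acquisition.blur_kernel_sd, acquisition.blur_kernel_sd)
        )

    amp_scale = float(np.mean([tp.amplitude for tp in resolved]))
    if acquisition.baseline_drift_rate:
        drift = acquisition.baseline_drift_rate * amp_scale * (t_ms / 1000.0)
        frames[:, layout.mask] += drift[:, None]
    if acquisition.noise_sd:
        rng = np.random.default_rng(noise_ss)
        frames += acquisition.noise_sd * amp_scale * rng.standard_normal(frames.shape)
    frames *= acquisition.polarity

    movie = Movie(frames=frames, frame_rate=acquisition.frame_rate, mask=layout.mask.copy())
    truth = SyntheticTruth(
        region_labels=layout.region_labels.copy(),
        templates=resolved,
        schedule=schedule,
        acquisition=acquisition,
        seed=seed,
        event_times_s=events,
    )
    return movie, truth


def interior_mask(layout: ClusterLayout, radius: int = 2) -> np.ndarray:
    """Pixels whose whole (2*radius+1)^2 neighborhood lies in one region.

    Spatial filtering (boxcar, optical blur) mixes phenotypes near region
    borders and the mask edge; recovery of planted per-pixel truth is
    only well-posed at these interior pixels.  ``radius`` should cover
    the filtering support (2 for a 5 x 5 boxcar, plus ~2 sigma of any
    Gaussian blur).
    """
    out = np.zeros(layout.mask.shape, dtype=bool)
    structure = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    for p in range(layout.n_phenotypes):
        region = layout.region_labels == p
        out |= ndimage.binary_erosion(region, structure=structure)
    return out


# ---------------------------------------------------------------------------
# phenotype library

#: (APD30 ms, APD80 ms) targets spanning the observed phenotype ranges
#: (APD30 46-188 ms, APD80 85-257 ms, triangulation 45-117 ms, fractional
#: repolarization 0.27-0.51).
PRESET_TARGETS: dict[str, tuple[float, float]] = {
    "compact_short": (46.0, 85.0),
    "short_triangular": (50.0, 100.0),
    "triangular": (57.0, 117.0),
    "intermediate": (85.0, 137.0),
    "long_plateau": (150.0, 220.0),
    "broad_triangular": (110.0, 227.0),
    "long_plateau_extreme": (188.0, 257.0),
}


def preset_template(name: str, amplitude: float = 1.0) -> APTemplate:
    """Resolved template for one of the named phenotype presets."""
    try:
        a30, a80 = PRESET_TARGETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESET_TARGETS)}") from None
    return resolve_template(
        APTemplate(target_apd30=a30, target_apd80=a80, amplitude=amplitude)
    )
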