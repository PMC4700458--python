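"""Per-site action-potential parameters and their rate dependence.

Four parameters quantify each averaged AP: duration at 30% and 80%
repolarization (APD30, APD80), triangulation (time from APD30 to APD80),
and fractional repolarization (triangulation / APD80).  Triangulation is
referenced to APD80 rather than APD90 because optically recorded APs can
carry a slow repolarizing tail that makes deep levels unreliable.

All durations are measured from the activation time (instant of fastest
upstroke); level crossings are taken after the waveform peak, first
crossing only, with linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AveragedAP

__all__ = [
    "APParameters",
    "RateDependence",
    "UnresolvedRepolarizationError",
    "apd_from_waveform",
    "compute_apd",
    "compute_parameters",
    "parameters_table",
    "fit_rate_dependence",
    "FLAT_APD80_SLOPE_MS_PER_BPM",
    "FLAT_FRAC_SLOPE_PER_BPM",
]

#: |slope| below these are classified "flat" (guard band against noise;
#: units ms/bpm and 1/bpm).
FLAT_APD80_SLOPE_MS_PER_BPM = 0.05
FLAT_FRAC_SLOPE_PER_BPM = 2.5e-4


class UnresolvedRepolarizationError(ValueError):
    """The waveform never repolarizes to the requested level in the window."""


@dataclass
class APParameters:
    """The four AP parameters of one site.

    Invariants: 0 < apd30 < apd80; triangulation = apd80 - apd30 exactly;
    fractional_repolarization = triangulation / apd80 in (0, 1).
    """

    apd30: float
    apd80: float
    triangulation: float
    fractional_repolarization: float
    site: tuple[int, int] | None = None
    cluster_id: str | None = None
    pacing_rate_bpm: float | None = None


@dataclass
class RateDependence:
    """Least-squares rate dependence of APD80 and fractional repolarization.

    Slopes are fitted over the pacing rates (bpm); each sign is
    "positive", "negative", or "flat" when the magnitude falls below the
    tolerance for that parameter.
    """

    rates: np.ndarray
    apd80_by_rate: np.ndarray
    frac_repol_by_rate: np.ndarray
    apd80_slope: float
    frac_slope: float
    apd80_slope_sign: str
    frac_slope_sign: str


def apd_from_waveform(
    values: np.ndarray,
    dt_ms: float,
    t_act_index: float,
    repol_fraction: float,
    baseline: float | None = None,
) -> float:
    """APD at ``repol_fraction`` for a waveform sampled every ``dt_ms``.

    ``t_act_index`` is the (possibly fractional) sample index of the
    activation time.  Amplitude is peak minus baseline; the crossing level
    is baseline + (1 - repol_fraction) * amplitude, searched forward from
    the post-activation peak and linearly interpolated.
    """
    if not 0 < repol_fraction < 1:
        raise ValueError("repol_fraction must lie in (0, 1)")
    v = np.asarray(values, dtype=float)
    start = int(np.ceil(t_act_index))
    if start >= v.size - 1:
        raise ValueError("activation index outside waveform")
    if baseline is None:
        pre = v[: max(1, int(np.floor(t_act_index)))]
        baseline = float(np.median(pre[pre <= np.quantile(pre, 0.5)])) if pre.size else 0.0
    peak_idx = start + int(np.argmax(v[start:]))
    peak = v[peak_idx]
    amplitude = peak - baseline
    if amplitude <= 0:
        raise UnresolvedRepolarizationError("non-positive amplitude")
    level = baseline + (1.0 - repol_fraction) * amplitude
    seg = v[peak_idx:]
    below = np.flatnonzero(seg[1:] <= level)
    for j in below:
        hi, lo = seg[j], seg[j + 1]
        if hi > level >= lo:
            frac = (hi - level) / (hi - lo)
            t_cross = (peak_idx + j + frac) * dt_ms
            return t_cross - t_act_index * dt_ms
        if hi <= level:  # already at/below level at the peak-adjacent sample
            return (peak_idx + j) * dt_ms - t_act_index * dt_ms
    raise UnresolvedRepolarizationError(
        f"waveform never falls to {1 - repol_fraction:.2f} of amplitude"
    )


def compute_apd(ap: AveragedAP, repol_fraction: float) -> float:
    """AP duration (ms) of an averaged AP at the given repolarization level.

    Measured from the waveform's stored activation reference; e.g.
    repol_fraction 0.30 gives APD30 (crossing of 70% of amplitude).
    """
    return apd_from_waveform(ap.values, ap.dt_ms, ap.t_act_index, repol_fraction)


def compute_parameters(
    ap: AveragedAP,
    cluster_id: str | None = None,
    pacing_rate_bpm: float | None = None,
) -> APParameters:
    """All four AP parameters of one averaged AP."""
    apd30 = compute_apd(ap, 0.30)
    apd80 = compute_apd(ap, 0.80)
    if not 0 < apd30 < apd80:
        raise UnresolvedRepolarizationError(
            f"inconsistent durations: APD30={apd30:.2f}, APD80={apd80:.2f}"
        )
    tri = apd80 - apd30
    return APParameters(
        apd30=apd30,
        apd80=apd80,
        triangulation=tri,
        fractional_repolarization=tri / apd80,
        site=ap.site,
        cluster_id=cluster_id,
        pacing_rate_bpm=pacing_rate_bpm,
    )


def parameters_table(params: list[APParameters], n_beats: np.ndarray | None = None) -> pd.DataFrame:
    """Tidy per-site parameter table (one row per site and pacing rate)."""
    rows = []
    for i, p in enumerate(params):
        r, c = p.site if p.site is not None else (-1, -1)
        rows.append(
            {
                "cluster_id": p.cluster_id,
                "site_row": r,
                "site_col": c,
                "pacing_rate_bpm": p.pacing_rate_bpm,
                "apd30_ms": p.apd30,
                "apd80_ms": p.apd80,
                "triangulation_ms": p.triangulation,
                "fractional_repolarization": p.fractional_repolarization,
                "n_beats": None if n_beats is None else int(n_beats[i]),
            }
        )
    return pd.DataFrame(rows)


def _sign(slope: float, tol: float) -> str:
    if abs(slope) < tol:
        return "flat"
    return "positive" if slope > 0 else "negative"


def fit_rate_dependence(params_by_rate: list[APParameters]) -> RateDependence:
    """Least-squares rate dependence of one site's APD80 and fractional
    repolarization across pacing rates.

    Requires parameters at >= 2 distinct rates.  In working myocardium
    APD80 typically shortens with rate (negative restitution slope);
    fractional repolarization can go either way, which is what makes its
    slope sign a discriminating feature between phenotypes.
    """
    rates = np.array([p.pacing_rate_bpm for p in params_by_rate], dtype=float)
    if np.unique(rates).size < 2:
        raise ValueError("need parameters at >= 2 distinct pacing rates")
    apd80 = np.array([p.apd80 for p in params_by_rate])
    frac = np.array([p.fractional_repolarization for p in params_by_rate])
    apd80_slope = float(np.polyfit(rates, apd80, 1)[0])
    frac_slope = float(np.polyfit(rates, frac, 1)[0])
    return RateDependence(
        rates=rates,
        apd80_by_rate=apd80,
        frac_repol_by_rate=frac,
        apd80_slope=apd80_slope,
        frac_slope=frac_slope,
        apd80_slope_sign=_sign(apd80_slope, FLAT_APD80_SLOPE_MS_PER_BPM),
        frac_slope_sign=_sign(frac_slope, FLAT_FRAC_SLOPE_PER_BPM),
    )
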