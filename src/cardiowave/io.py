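"""HDF5 and JSON file formats for movies, averaged APs, and ground truth.

Movie container layout:
    /frames            T x H x W float32
    /mask              H x W bool
    /truth/region_labels   (optional) H x W int
    attrs: frame_rate_fps, pixel_pitch_um, polarity
plus an optional ``<file>.truth.json`` sidecar holding the templates and
pacing schedule of a synthetic movie.

Averaged-AP container layout:
    /aps               n_sites x L float64 (normalized waveforms)
    /sites             n_sites x 2 int (row, col)
    /n_beats           n_sites int
    /activations/site_<i>   per-site activation times (ms)
    attrs: frame_rate_fps, pre_ms, post_ms
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import ActivationTimes, Movie, PreprocessResult
from .synthetic import AcquisitionConfig, APTemplate, PacingSchedule, SyntheticTruth

__all__ = [
    "write_movie",
    "read_movie",
    "read_truth_labels",
    "write_aps",
    "read_aps",
]


def write_movie(
    path: str | Path,
    movie: Movie,
    truth: SyntheticTruth | None = None,
    pixel_pitch_um: float = 16.0,
    polarity: int = 1,
) -> None:
    """Write a movie (and optional synthetic ground truth) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.frames.astype(np.float32), compression="gzip")
        f.create_dataset("mask", data=movie.mask)
        f.attrs["frame_rate_fps"] = movie.frame_rate
        f.attrs["pixel_pitch_um"] = pixel_pitch_um
        f.attrs["polarity"] = polarity
        if truth is not None:
            f.create_dataset("truth/region_labels", data=truth.region_labels)
    if truth is not None:
        sidecar = {
            "seed": truth.seed,
            "templates": [dataclasses.asdict(t) for t in truth.templates],
            "schedule": dataclasses.asdict(truth.schedule),
            "acquisition": dataclasses.asdict(truth.acquisition),
            "event_times_s": np.asarray(truth.event_times_s).tolist(),
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps(sidecar, indent=2)
        )


def read_movie(path: str | Path) -> tuple[Movie, int]:
    """Read a movie container; returns the movie and its recorded polarity."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    with h5py.File(path, "r") as f:
        movie = Movie(
            frames=f["frames"][...].astype(float),
            frame_rate=float(f.attrs["frame_rate_fps"]),
            mask=f["mask"][...].astype(bool),
        )
        polarity = int(f.attrs.get("polarity", 1))
    return movie, polarity


def read_truth_labels(path: str | Path) -> np.ndarray | None:
    """Planted region labels of a synthetic movie, if present."""
    with h5py.File(path, "r") as f:
        if "truth/region_labels" in f:
            return f["truth/region_labels"][...]
    return None


def read_truth_sidecar(path: str | Path) -> SyntheticTruth | None:
    """Reconstruct the full SyntheticTruth from container + JSON sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    labels = read_truth_labels(path)
    if labels is None or not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    return SyntheticTruth(
        region_labels=labels,
        templates=[APTemplate(**t) for t in meta["templates"]],
        schedule=PacingSchedule(**{**meta["schedule"],
                                   "rates": tuple(meta["schedule"]["rates"])}),
        acquisition=AcquisitionConfig(**meta["acquisition"]),
        seed=meta["seed"],
        event_times_s=np.asarray(meta["event_times_s"]),
    )


def write_aps(path: str | Path, result: PreprocessResult) -> None:
    """Write a per-site averaged-AP matrix with activation times to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("aps", data=result.aps)
        f.create_dataset("sites", data=np.asarray(result.sites, dtype=int))
        f.create_dataset("n_beats", data=result.n_beats)
        f.attrs["frame_rate_fps"] = result.frame_rate
        f.attrs["pre_ms"] = result.pre_ms
        f.attrs["post_ms"] = result.post_ms
        grp = f.create_group("activations")
        for i, act in enumerate(result.activations):
            grp.create_dataset(f"site_{i}", data=act.times_ms)
            grp.create_dataset(f"site_{i}_velocity", data=act.upstroke_velocities)


def read_aps(path: str | Path) -> PreprocessResult:
    """Read back an averaged-AP container written by :func:`write_aps`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"AP file not found: {path}")
    with h5py.File(path, "r") as f:
        aps = f["aps"][...]
        sites = [tuple(int(v) for v in row) for row in f["sites"][...]]
        n_beats = f["n_beats"][...]
        acts = []
        grp = f["activations"]
        for i in range(aps.shape[0]):
            acts.append(ActivationTimes(
                times_ms=grp[f"site_{i}"][...],
                upstroke_velocities=grp[f"site_{i}_velocity"][...],
            ))
        return PreprocessResult(
            aps=aps,
            sites=sites,
            frame_rate=float(f.attrs["frame_rate_fps"]),
            pre_ms=float(f.attrs["pre_ms"]),
            post_ms=float(f.attrs["post_ms"]),
            n_beats=n_beats,
            activations=acts,
        )
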