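"""Shared fixtures: small synthetic clusters with planted ground truth.

Heavy simulations are session-scoped so unit and acceptance tests reuse
them.  All randomness is seeded; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiowave import pipeline, synthetic as syn

SHORT = "short_triangular"  # planted APD30/APD80 = 50/100 ms
LONG = "long_plateau"  # planted APD30/APD80 = 150/220 ms


@pytest.fixture(scope="session")
def short_template():
    return syn.preset_template(SHORT)


@pytest.fixture(scope="session")
def long_template():
    return syn.preset_template(LONG)


def make_two_phenotype_movie(noise_sd: float, blur_sd: float, seed: int,
                             size: int = 24, drift: float = 0.0,
                             record_s: float = 8.0):
    """One 90-bpm-paced cluster split into short-AP and long-AP halves."""
    layout = syn.split_layout(syn.elliptical_mask(size, size), 2)
    templates = [syn.preset_template(SHORT), syn.preset_template(LONG)]
    schedule = syn.PacingSchedule(mode="paced", rates=(90.0,), record_duration=record_s)
    acq = syn.AcquisitionConfig(height=size, width=size, noise_sd=noise_sd,
                                blur_kernel_sd=blur_sd, baseline_drift_rate=drift)
    movie, truth = syn.generate_cluster_movie(layout, templates, schedule, acq, seed=seed)
    return movie, truth, layout


@pytest.fixture(scope="session")
def noiseless_cluster():
    """Noise-free, blur-free two-phenotype movie: planted APDs should be
    recovered almost exactly at interior sites."""
    return make_two_phenotype_movie(noise_sd=0.0, blur_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_cluster():
    return make_two_phenotype_movie(noise_sd=0.05, blur_sd=0.0, seed=12)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_cluster):
    movie, truth, layout = noiseless_cluster
    pre, table = pipeline.analyze_movie(movie, cluster_id="c0", pacing_rate_bpm=90.0)
    return pre, table, truth, layout


@pytest.fixture(scope="session")
def pooled_population():
    """Eight two-phenotype clusters (APD80 120 ms apart, noise 0.05, blur 1 px)
    pooled into one AP population with planted phenotype labels."""
    aps, labels, apd30, apd80 = [], [], [], []
    for i in range(8):
        movie, truth, layout = make_two_phenotype_movie(
            noise_sd=0.05, blur_sd=1.0, seed=100 + i)
        pre, table = pipeline.analyze_movie(movie, cluster_id=f"c{i}",
                                            pacing_rate_bpm=90.0)
        idx = table["site_index"].to_numpy()
        site_labels = truth.region_labels[tuple(np.array(pre.sites).T)][idx]
        aps.append(pre.aps[idx])
        labels.append(site_labels)
        apd30.append(table["apd30_ms"].to_numpy())
        apd80.append(table["apd80_ms"].to_numpy())
    return {
        "aps": np.vstack(aps),
        "true_labels": np.concatenate(labels),
        "apd30": np.concatenate(apd30),
        "apd80": np.concatenate(apd80),
    }
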