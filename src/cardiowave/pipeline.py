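"""End-to-end orchestration: simulate -> preprocess -> metrics -> group -> report.

A run is driven by a :class:`RunConfig`, writes every artifact (config
copy, per-cluster AP containers, tidy parameter CSV, label CSV, fit
JSON, summary table, figures) into one output directory, and is
reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grouping, io, metrics, synthetic
from .pipeline_constants import PARAM_COLUMNS
from .preprocess import PreprocessResult, preprocess_movie

logger = logging.getLogger("cardiowave")

__all__ = [
    "RunConfig",
    "ClusterSpec",
    "default_benchmark_config",
    "run_pipeline",
    "summarize_table",
    "analyze_movie",
    "PARAM_COLUMNS",
]


@dataclass
class ClusterSpec:
    """Simulation recipe for one synthetic cluster: its phenotype presets
    (one or two; two split the mask into spatial halves) and geometry."""

    cluster_id: str
    presets: tuple[str, ...] = ("short_triangular", "long_plateau")
    height: int = 24
    width: int = 24

    def layout(self) -> synthetic.ClusterLayout:
        mask = synthetic.elliptical_mask(self.height, self.width)
        return synthetic.split_layout(mask, n_regions=len(self.presets),
                                      cluster_id=self.cluster_id)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized for provenance)."""

    clusters: list[ClusterSpec]
    pacing_rate_bpm: float = 90.0
    record_duration_s: float = 8.0
    frame_rate: float = 500.0
    noise_sd: float = 0.02
    blur_kernel_sd: float = 1.0
    baseline_drift_rate: float = 0.005
    window: tuple[float, float] = (50.0, 600.0)
    methods: tuple[str, ...] = ("apd80_threshold", "pca_threshold", "waveform_spectral")
    k_values: tuple[int, ...] = (2, 3)
    seed: int = 0
    out_dir: str = "runs/run0"
    make_figures: bool = True
    save_movies: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def default_benchmark_config(seed: int = 0, out_dir: str = "runs/benchmark",
                             n_clusters: int = 8) -> RunConfig:
    """Default synthetic benchmark: a pool of clusters, most containing two
    spatially segregated phenotypes, paced at 90 bpm.

    Phenotype assignments cycle through the preset library so the pooled
    population spans the observed APD ranges.
    """
    names = list(synthetic.PRESET_TARGETS)
    clusters = []
    for i in range(n_clusters):
        if i % 4 == 3:  # every fourth cluster is homogeneous
            presets: tuple[str, ...] = (names[i % len(names)],)
        else:
            presets = (names[i % len(names)], names[(i + 3) % len(names)])
        clusters.append(ClusterSpec(cluster_id=f"cluster{i:02d}", presets=presets))
    return RunConfig(clusters=clusters, seed=seed, out_dir=out_dir)


def analyze_movie(
    movie, polarity: int = 1, window: tuple[float, float] = (50.0, 600.0),
    cluster_id: str | None = None, pacing_rate_bpm: float | None = None,
) -> tuple[PreprocessResult, pd.DataFrame]:
    """Condition one movie and extract the per-site AP parameter table."""
    pre = preprocess_movie(movie, polarity=polarity, window=window)
    params = []
    keep = []
    for i in range(pre.aps.shape[0]):
        try:
            p = metrics.compute_parameters(pre.averaged_ap(i), cluster_id=cluster_id,
                                           pacing_rate_bpm=pacing_rate_bpm)
        except metrics.UnresolvedRepolarizationError:
            continue
        params.append(p)
        keep.append(i)
    table = metrics.parameters_table(params, n_beats=pre.n_beats[keep])
    table["site_index"] = keep
    return pre, table


def _simulate_cluster(spec: ClusterSpec, config: RunConfig, seed_seq) -> tuple:
    layout = spec.layout()
    templates = [synthetic.preset_template(name) for name in spec.presets]
    schedule = synthetic.PacingSchedule(
        mode="paced", rates=(config.pacing_rate_bpm,),
        record_duration=config.record_duration_s,
    )
    acq = synthetic.AcquisitionConfig(
        frame_rate=config.frame_rate, height=spec.height, width=spec.width,
        noise_sd=config.noise_sd, blur_kernel_sd=config.blur_kernel_sd,
        baseline_drift_rate=config.baseline_drift_rate,
    )
    child_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    movie, truth = synthetic.generate_cluster_movie(layout, templates, schedule, acq,
                                                    seed=child_seed)
    return movie, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a result dict with the parameter table, grouping results,
    and summary table; writes all artifacts under ``config.out_dir``.
    Any stage failure aborts with the failing stage named; artifacts
    written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    stage = "simulate"
    t0 = time.time()
    try:
        root_ss = np.random.SeedSequence(config.seed)
        cluster_seeds = root_ss.spawn(len(config.clusters))
        tables = []
        pres: dict[str, PreprocessResult] = {}
        truths = {}
        for spec, ss in zip(config.clusters, cluster_seeds):
            movie, truth = _simulate_cluster(spec, config, ss)
            if config.save_movies:
                (out / "movies").mkdir(exist_ok=True)
                io.write_movie(out / "movies" / f"{spec.cluster_id}.h5", movie, truth)
            stage = "preprocess"
            pre, table = analyze_movie(movie, window=config.window,
                                       cluster_id=spec.cluster_id,
                                       pacing_rate_bpm=config.pacing_rate_bpm)
            truth_lab = truth.region_labels[tuple(np.array(pre.sites).T)]
            table["true_phenotype"] = truth_lab[table["site_index"].to_numpy()]
            pres[spec.cluster_id] = pre
            truths[spec.cluster_id] = truth
            tables.append(table)
            logger.info("cluster %s: %d sites, %d beats averaged (median)",
                        spec.cluster_id, len(table), int(np.median(pre.n_beats)))
            stage = "simulate"
        stage = "metrics"
        params = pd.concat(tables, ignore_index=True)
        params.to_csv(out / "params.csv", index=False)

        stage = "group"
        pooled_aps = np.vstack([
            pres[cid].aps[params.loc[params.cluster_id == cid, "site_index"]]
            for cid in params["cluster_id"].unique()
        ])
        label_rows = []
        fits: dict[str, dict] = {}
        for k in config.k_values:
            results = grouping.group_population(
                pooled_aps, params["apd30_ms"].to_numpy(), params["apd80_ms"].to_numpy(),
                k=k, methods=config.methods, seed=config.seed,
            )
            for method, res in results.items():
                fits[f"{method}_k{k}"] = {"dbi": res.dbi, **res.details}
                for i, lab in enumerate(res.labels):
                    label_rows.append({
                        "cluster_id": params["cluster_id"].iloc[i],
                        "site_row": params["site_row"].iloc[i],
                        "site_col": params["site_col"].iloc[i],
                        "method": method, "k": k, "label": int(lab),
                    })
        labels_df = pd.DataFrame(label_rows)
        labels_df.to_csv(out / "labels.csv", index=False)

        # SVM boundaries + overlap in every parameter pair, using the
        # k=2 waveform labels when available
        overlaps = []
        ref = None
        for k in config.k_values:
            key = f"waveform_spectral_k{k}"
            if key in fits and k == 2:
                ref = labels_df[(labels_df.method == "waveform_spectral") & (labels_df.k == 2)]
        if ref is not None and ref["label"].nunique() == 2:
            lab = ref["label"].to_numpy()
            for i, pa in enumerate(PARAM_COLUMNS):
                for pb in PARAM_COLUMNS[i + 1:]:
                    bo = grouping.svm_overlap(
                        params[[pa, pb]].to_numpy(), lab, parameter_pair=(pa, pb))
                    overlaps.append({
                        "param_x": pa, "param_y": pb,
                        "overlap_percent": bo.overlap_percent,
                        "coef_x": bo.boundary[0], "coef_y": bo.boundary[1],
                        "intercept": bo.boundary[2],
                    })
        overlap_df = pd.DataFrame(overlaps)
        overlap_df.to_csv(out / "overlap.csv", index=False)
        (out / "groups.json").write_text(json.dumps(fits, indent=2, default=float))

        stage = "report"
        summary = summarize_table(params)
        summary.to_csv(out / "summary.csv", index=False)
        if config.make_figures:
            from . import report
            report.render_report(out, params, labels_df, overlap_df, fits, pres)
        logger.info("pipeline finished in %.1f s (%d clusters, %d sites)",
                    time.time() - t0, len(config.clusters), len(params))
        return {
            "params": params, "labels": labels_df, "overlap": overlap_df,
            "fits": fits, "summary": summary, "preprocess": pres, "truths": truths,
            "pooled_aps": pooled_aps,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc


def run_rate_sweep(
    layout: synthetic.ClusterLayout,
    targets_by_region: list[dict[float, tuple[float, float]]],
    acquisition: synthetic.AcquisitionConfig,
    seed: int = 0,
    record_duration_s: float = 6.0,
    pre_ms: float = 50.0,
    max_post_ms: float = 600.0,
) -> pd.DataFrame:
    """Pace one cluster at several rates and fit per-site rate dependence.

    ``targets_by_region[p]`` maps pacing rate (bpm) to the (APD30, APD80)
    targets of phenotype ``p`` at that rate, emulating region-specific
    restitution.  Each rate is simulated and analyzed as a separate
    recording; the averaging window shrinks to 85% of the cycle length at
    fast rates so consecutive beats stay out of the window.  Returns one
    row per site present at every rate, with fitted slopes, slope signs,
    and the planted phenotype label.
    """
    rates = sorted(targets_by_region[0])
    tables = []
    for rate in rates:
        templates = [
            synthetic.resolve_template(synthetic.APTemplate(
                target_apd30=tgt[rate][0], target_apd80=tgt[rate][1]))
            for tgt in targets_by_region
        ]
        schedule = synthetic.PacingSchedule(mode="paced", rates=(rate,),
                                            record_duration=record_duration_s)
        movie, truth = synthetic.generate_cluster_movie(
            layout, templates, schedule, acquisition, seed=seed, rate_bpm=rate)
        post = min(max_post_ms, 0.85 * 60000.0 / rate)
        pre, table = analyze_movie(movie, window=(pre_ms, post), pacing_rate_bpm=rate,
                                   cluster_id=layout.cluster_id)
        table["true_phenotype"] = truth.region_labels[
            tuple(np.array(pre.sites).T)][table["site_index"].to_numpy()]
        tables.append(table)
    merged = pd.concat(tables, ignore_index=True)
    rows = []
    for (r, c), site_tab in merged.groupby(["site_row", "site_col"]):
        if site_tab["pacing_rate_bpm"].nunique() < len(rates):
            continue
        params = [
            metrics.APParameters(
                apd30=row.apd30_ms, apd80=row.apd80_ms,
                triangulation=row.triangulation_ms,
                fractional_repolarization=row.fractional_repolarization,
                site=(int(r), int(c)), pacing_rate_bpm=row.pacing_rate_bpm)
            for row in site_tab.itertuples()
        ]
        rd = metrics.fit_rate_dependence(params)
        rows.append({
            "site_row": int(r), "site_col": int(c),
            "apd80_slope": rd.apd80_slope, "frac_slope": rd.frac_slope,
            "apd80_slope_sign": rd.apd80_slope_sign,
            "frac_slope_sign": rd.frac_slope_sign,
            "true_phenotype": int(site_tab["true_phenotype"].iloc[0]),
        })
    return pd.DataFrame(rows)


def summarize_table(params: pd.DataFrame) -> pd.DataFrame:
    """Population summary of the four AP parameters across clusters.

    For each parameter: the range of per-cluster means (Individual Mean),
    the pooled mean over all sites (Overall Mean), the range of
    per-cluster SDs (Individual SD), and the pooled SD (Overall SD).
    With a single cluster the individual ranges collapse to a point.
    """
    rows = []
    by_cluster = params.groupby("cluster_id")
    for col in PARAM_COLUMNS:
        means = by_cluster[col].mean()
        sds = by_cluster[col].std(ddof=1).fillna(0.0)
        rows.append({
            "parameter": col,
            "individual_mean_min": means.min(),
            "individual_mean_max": means.max(),
            "overall_mean": params[col].mean(),
            "individual_sd_min": sds.min(),
            "individual_sd_max": sds.max(),
            "overall_sd": params[col].std(ddof=1),
            "n_clusters": by_cluster.ngroups,
            "n_sites": len(params),
        })
    return pd.DataFrame(rows)
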