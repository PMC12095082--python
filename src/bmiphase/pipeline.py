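"""End-to-end orchestration: simulate, preprocess, distances, cluster, features.

The pipeline mirrors the published analysis flow: measurement selection ->
per-child curve fitting and QC -> BMI on the standard grid -> sex-stratified
pairwise phase distances -> PAM with silhouette selection of k -> trajectory
features and cluster summaries.  Every run writes headered CSVs plus a JSON
manifest (config, seed, per-stage counts) so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import zlib

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import elastic as _elastic
from . import features as _features
from . import preprocess as _pre
from .cohort_synth import SimConfig, TemplateParams, simulate_cohort

log = logging.getLogger("bmiphase")

__all__ = ["PipelineConfig", "run_simulate", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; mirrors the YAML config layout."""

    input_csv: str | None = None
    output_dir: str = "results"
    # preprocessing
    age_unit: str = "years"               # years | months | days (input file)
    interpolation: str = "bspline"        # bspline | linear
    degree: int = 3
    interior_knots_months: tuple = _pre.INTERIOR_KNOTS_MONTHS
    birth_epsilon: float = _pre.BIRTH_EPSILON
    series_rule: str = "both"
    height_drop_cm: float = _pre.HEIGHT_DROP_CM
    weight_drop_kg: float = _pre.WEIGHT_DROP_KG
    # elastic
    n_points: int = _elastic.DEFAULT_N_POINTS
    neighborhood_width: int = _elastic.DEFAULT_NEIGHBORHOOD
    z_normalize: bool = False
    # clustering
    kmin: int = 2
    kmax: int = 10
    k_override: dict = field(default_factory=dict)   # per sex: {"F": 3, "M": 3}
    stratify_by_sex: bool = True
    # simulation
    simulate: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self):
        if self.kmin < 2 or self.kmax < self.kmin:
            raise ValueError("need kmin >= 2 and kmax >= kmin")
        if self.interpolation not in ("bspline", "linear"):
            raise ValueError("interpolation must be 'bspline' or 'linear'")


def load_config(path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulate", {})
    if "cluster_params" in sim_raw:
        sim_raw["cluster_params"] = tuple(TemplateParams(**p)
                                          for p in sim_raw["cluster_params"])
    if "visit_schedule" in sim_raw:
        sim_raw["visit_schedule"] = tuple(sim_raw["visit_schedule"])
    sim = SimConfig(**sim_raw)
    return PipelineConfig(simulate=sim, **raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (< 2**31), deterministically."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_simulate(config: PipelineConfig, output_dir=None):
    """Generate a synthetic cohort and write measurements.csv + truth.csv."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulate,
                              seed=_stage_seed(config.seed, "simulate"))
    log.info("simulating cohort: %d children x %d clusters, seed %d",
             sim.n_per_cluster, len(sim.cluster_params), sim.seed)
    cohort = simulate_cohort(sim)
    cohort.records.df.to_csv(outdir / "measurements.csv", index=False)
    (cohort.true_labels.rename_axis("child_id").reset_index()
     .to_csv(outdir / "truth.csv", index=False))
    return cohort


def _run_stratum(bmi: _pre.BMIGrid, cfg: PipelineConfig, sex: str, outdir: Path):
    tag = f"_{sex}" if sex else ""
    log.info("stratum %s: %d children -> pairwise distances", sex or "all",
             len(bmi.child_ids))
    D = _elastic.pairwise_distance_matrix(bmi, cfg.n_points, cfg.neighborhood_width,
                                          cfg.z_normalize)
    dist_df = pd.DataFrame(np.round(D.D, 6), index=D.ids, columns=D.ids)
    dist_df.to_csv(outdir / f"distances{tag}.csv")
    assignment, table = _cluster.select_k(D, cfg.kmin, min(cfg.kmax, len(D.ids) - 1),
                                          cfg.k_override.get(sex))
    log.info("stratum %s: k*=%d (avg silhouette %.3f)", sex or "all",
             assignment.k, assignment.avg_silhouette)
    table.rows.to_csv(outdir / f"silhouette_by_k{tag}.csv", index=False)
    lab = assignment.to_frame()
    lab.insert(1, "sex", sex or "all")
    lab.to_csv(outdir / f"labels{tag}.csv", index=False)
    pd.DataFrame({"cluster": range(1, assignment.k + 1),
                  "medoid_id": assignment.medoid_ids}) \
        .to_csv(outdir / f"medoids{tag}.csv", index=False)
    pd.DataFrame({"child_id": _cluster.order_for_heatmap(D, assignment)}) \
        .to_csv(outdir / f"heatmap_order{tag}.csv", index=False)
    feats = _features.features_table(bmi)
    feats.to_csv(outdir / f"features{tag}.csv", index=False)
    _features.summarize_features_by_cluster(feats, assignment, sex or "all") \
        .to_csv(outdir / f"cluster_summary{tag}.csv", index=False)
    _features.peak_count_table(feats, assignment) \
        .to_csv(outdir / f"peak_counts{tag}.csv", index=False)
    _features.aligned_cross_sections(bmi, assignment, cfg.n_points,
                                     cfg.neighborhood_width) \
        .to_csv(outdir / f"aligned_means{tag}.csv", index=False)
    return assignment, table


def run_pipeline(config: PipelineConfig, input_csv=None, output_dir=None) -> dict:
    """Run the full analysis on a measurements file; returns stage results.

    Stages per sex stratum: selection -> fitting -> QC -> BMI grid ->
    distances -> silhouette model selection + PAM -> features -> summaries.
    All output tables are written under the output directory together with a
    run manifest.
    """
    path = input_csv or config.input_csv
    if path is None:
        raise ValueError("no input measurements file configured")
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _pre.GrowthRecordSet(pd.read_csv(path), age_unit=config.age_unit)
    log.info("loaded %d rows / %d children from %s", len(records),
             len(records.child_ids), path)
    try:
        bmi, report, qc = _pre.preprocess_cohort(
            records, mode=config.interpolation, degree=config.degree,
            interior_knots_months=config.interior_knots_months,
            birth_epsilon=config.birth_epsilon, series_rule=config.series_rule,
            height_drop_cm=config.height_drop_cm,
            weight_drop_kg=config.weight_drop_kg)
    except Exception as exc:
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc
    report.to_frame().to_csv(outdir / "selection_report.csv", index=False)
    qc.to_csv(outdir / "qc_flags.csv", index=False)
    bmi.to_frame().to_csv(outdir / "bmi_grid.csv", index=False)
    log.info("selection/QC kept %d of %d children", len(bmi.child_ids),
             len(records.child_ids))

    results = {"bmi_grid": bmi, "selection": report, "qc": qc, "strata": {}}
    strata = (sorted(set(bmi.sex)) if config.stratify_by_sex else [""])
    for sex in strata:
        sub = bmi.subset([s == sex for s in bmi.sex]) if sex else bmi
        if len(sub.child_ids) < max(3, config.kmin + 1):
            log.warning("stratum %s has %d children; skipped", sex,
                        len(sub.child_ids))
            continue
        try:
            assignment, table = _run_stratum(sub, config, sex, outdir)
        except Exception as exc:
            raise RuntimeError(f"clustering stage failed for stratum "
                               f"{sex or 'all'}: {exc}") from exc
        results["strata"][sex or "all"] = {"assignment": assignment,
                                           "silhouettes": table}
    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "seed": config.seed,
        "python": platform.python_version(),
        "n_input_children": len(records.child_ids),
        "n_kept": len(bmi.child_ids),
        "strata": {s: {"n": int(np.sum([x == (s if s != 'all' else x) for x in bmi.sex]))
                       if s != "all" else len(bmi.child_ids),
                       "k": r["assignment"].k,
                       "avg_silhouette": r["assignment"].avg_silhouette}
                   for s, r in results["strata"].items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
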