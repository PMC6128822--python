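"""End-to-end orchestration: synthetic cohort -> GLM -> cluster correction ->
hotspots -> topography -> TMS coverage, with a JSON-serializable run report.

Two entry modes:

* ``coordinate`` — the fast path: hotspot coordinates are drawn directly from
  the spatial mixture (no images), exercising topography and coverage;
* ``image`` — the full path: per-subject 4D simulation, first-level GLM,
  Monte-Carlo extent correction, hotspot extraction, then the same
  downstream analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clusters import apply_extent_threshold, label_clusters, monte_carlo_extent_threshold
from .config import PipelineConfig
from .coverage import format_coverage_report, subgroup_coverage
from .electrodes import load_electrodes
from .glm import fit_first_level
from .hotspots import HotspotSet, assemble_cohort, extract_hotspots, rank_clusters
from .paradigm import build_paradigm
from .synthetic import build_cohort, frontal_grid, sample_cohort_hotspots, simulate_timeseries
from .topography import cross_tab, select_k

log = logging.getLogger("cuetopo")

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Numeric results of one pipeline run, reproducible from its config."""

    config: dict
    counts: dict
    topography: dict
    contingency: dict
    coverage: dict
    subjects: list[dict] = field(default_factory=list)
    version: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "version": self.version, "config": self.config, "counts": self.counts,
            "topography": self.topography, "contingency": self.contingency,
            "coverage": self.coverage, "subjects": self.subjects,
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("cohort", "points", "mc_null", "images", "kmeans_full", "kmeans_restricted")
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(names, children)}


def _topography_block(hs: HotspotSet, cfg: PipelineConfig, seed: int) -> tuple[dict, dict]:
    km = cfg.kmeans
    k_max = min(int(km["k_max"]), max(int(km["k_min"]), len(hs) - 1))
    sol, diag = select_k(hs.coords, k_min=int(km["k_min"]), k_max=k_max,
                         n_restarts=int(km["n_restarts"]), seed=seed)
    shares = sol.cluster_shares()
    topo = {
        "selected_k": sol.k,
        "centroids_mm": sol.centroids.tolist(),
        "cluster_shares": shares.tolist(),
        "mean_silhouette": sol.mean_silhouette,
        "wcss": sol.wcss,
        "weak_structure": bool(diag["weak_structure"].iloc[0]),
        "per_k": diag[["k", "wcss", "mean_silhouette"]].to_dict(orient="records"),
    }
    contingency = {}
    for factor in ("group", "sex"):
        try:
            res = cross_tab(hs, sol, factor=factor)
            contingency[factor] = {
                "chi2": res.chi2, "df": res.df, "p": res.p,
                "low_expected_warning": res.low_expected_warning,
                "table": {str(k): [int(v) for v in row]
                          for k, row in zip(res.table.index, res.table.to_numpy())},
            }
        except ValueError as exc:
            contingency[factor] = {"error": str(exc)}
    return topo, contingency


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages for the configured mode and return the report."""
    seeds = _stage_seeds(config.seed)
    cohort = build_cohort(n_per_group={k: int(v) for k, v in config.cohort["n_per_group"].items()},
                          responder_rate=float(config.cohort["responder_rate"]),
                          spec=config.mixture_spec,
                          amplitude=float(config.cohort["amplitude"]),
                          seed=seeds["cohort"])
    log.info("cohort: %d subjects (%d responders by truth)",
             len(cohort), sum(s.responder for s in cohort))

    subjects_out: list[dict] = []
    if config.mode == "coordinate":
        full = sample_cohort_hotspots(cohort, config.mixture_spec, seed=seeds["points"])
        for s in cohort:
            subjects_out.append({
                "subject_id": s.subject_id, "group": s.group, "responder": s.responder,
                "true_locus_mm": None if s.true_locus is None else s.true_locus.tolist(),
            })
    else:
        full = _image_level_hotspots(cohort, config, seeds, subjects_out)

    restricted = full.restricted()
    log.info("hotspots: %d full complement, %d restricted (%d/%d responders)",
             len(full), len(restricted), full.responder_count, len(cohort))

    counts = {
        "n_subjects": len(cohort),
        "n_responders": full.responder_count,
        "responder_fraction": (full.responder_count / len(cohort)) if cohort else 0.0,
        "n_points_full": len(full),
        "n_points_restricted": len(restricted),
    }

    topo_full, conting_full = _topography_block(full, config, seeds["kmeans_full"])
    topography = {"full_complement": topo_full}
    contingency = {"full_complement": conting_full}
    if len(restricted) > int(config.kmeans["k_min"]):
        topo_r, conting_r = _topography_block(restricted, config, seeds["kmeans_restricted"])
        topography["one_per_individual"] = topo_r
        contingency["one_per_individual"] = conting_r

    electrodes = load_electrodes(config.electrodes, strict=False)
    tables = subgroup_coverage(full, electrodes, config.radii_mm, config.rounding)
    report_frame = format_coverage_report(tables)
    coverage = {
        "provenance": electrodes.provenance,
        "radii_mm": list(config.radii_mm),
        "best_by_group": {
            name: {f"{r:g}": {"electrodes": tab.best[r],
                              "percent": float(tab.coverage.loc[tab.best[r][0], r])}
                   for r in tab.radii_mm}
            for name, tab in tables.items()
        },
        "table": report_frame.to_dict(orient="records"),
    }

    report = RunReport(config=config.as_dict(), counts=counts, topography=topography,
                       contingency=contingency, coverage=coverage,
                       subjects=subjects_out, version=__version__)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        full.to_tsv(out / "hotspots_full.tsv")
        restricted.to_tsv(out / "hotspots_restricted.tsv")
    return report


def _image_level_hotspots(cohort, config: PipelineConfig, seeds: dict,
                          subjects_out: list[dict]) -> HotspotSet:
    acq = config.acquisition
    thr_cfg = config.thresholding
    paradigm = build_paradigm(n_epochs=int(config.paradigm["n_epochs"]),
                              block_s=float(config.paradigm["block_s"]),
                              epoch_s=float(config.paradigm["epoch_s"]),
                              epoch_fill=config.paradigm["epoch_fill"])
    grid = frontal_grid(voxel_mm=float(acq["voxel_mm"]))
    n_volumes = int(np.floor(paradigm.total_duration_s / float(acq["tr_s"])))
    from .paradigm import build_design
    design = build_design(paradigm, float(acq["tr_s"]), n_volumes)
    contrast = {"Drug": 1.0, "Neutral": -1.0}

    from .volume import MaskVolume, VolumeGrid
    mask = MaskVolume(VolumeGrid(np.ones(grid.shape), grid.affine))
    thr = monte_carlo_extent_threshold(
        mask, smoothness_fwhm_mm=float(acq["smoothness_fwhm_mm"]),
        voxel_p=float(thr_cfg["voxel_p"]), cluster_alpha=float(thr_cfg["cluster_alpha"]),
        n_iterations=int(thr_cfg["n_iterations"]),
        connectivity=int(thr_cfg["connectivity"]), seed=seeds["mc_null"])
    log.info("extent threshold: >= %d voxels (voxel p<%g, alpha %g)",
             thr.min_cluster_size_voxels, thr.voxel_p, thr.cluster_alpha)

    img_ss = np.random.SeedSequence(seeds["images"]).spawn(len(cohort))
    per_subject = []
    for s, child in zip(cohort, img_ss):
        data, submask = simulate_timeseries(
            s, paradigm, grid, tr_s=float(acq["tr_s"]),
            noise_sd=float(acq["noise_sd"]),
            smoothness_fwhm_mm=float(acq["smoothness_fwhm_mm"]),
            blob_fwhm_mm=float(acq["blob_fwhm_mm"]),
            seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        result = fit_first_level(data, design, contrast, submask)
        clusters = label_clusters(result.t, float(thr_cfg["voxel_p"]), submask,
                                  int(thr_cfg["connectivity"]))
        surviving = rank_clusters(apply_extent_threshold(clusters, thr))
        hs = extract_hotspots(result.t, surviving, submask, s.subject_id, s.group, s.sex)
        per_subject.append(hs)
        subjects_out.append({
            "subject_id": s.subject_id, "group": s.group, "responder": s.responder,
            "true_locus_mm": None if s.true_locus is None else s.true_locus.tolist(),
            "n_clusters": len(surviving),
            "hotspot_mm": hs[0].mm.tolist() if hs else None,
            "peak_t": hs[0].peak_t if hs else None,
        })
    return assemble_cohort(per_subject, mode="full_complement",
                           n_subjects_total=len(cohort))
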