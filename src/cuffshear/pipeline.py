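"""End-to-end orchestration: simulate -> metrics -> cohort analysis -> files.

:func:`analyze_cohort` is the in-memory core: it computes the raw metric
maps for every vessel, calibrates the LSI/HSI thresholds from the control
vessels, display-normalizes each metric, aggregates region means and runs
the cohort statistics.  :func:`run_full_pipeline` wraps it with file output
(STL geometry, WSS field CSVs, metric CSVs, thresholds JSON, the region
table, comparisons and en-face grids) and a provenance manifest.  The whole
pipeline is a pure function of (config, master seed); repeated runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cohort import ComparisonResult, floor_and_scale, region_means, \
    summarize_cohort
from .config import PipelineConfig
from .enface import enface
from .mesh import node_neighbors, write_stl
from .metrics import (
    METRIC_UNITS,
    MetricMap,
    TawssThresholds,
    compute_base_metrics,
    fit_thresholds,
    hsi,
    lsi,
    normalize_display,
)
from .synthetic import MouseDataset, VesselData, synth_cohort

logger = logging.getLogger(__name__)

#: Metrics whose display scale is the cohort-observed maximum.
OBSERVED_MAX_METRICS = ("TAWSS", "tSS", "RRT")

_FLOAT_FMT = "%.12g"


@dataclass
class CohortAnalysis:
    """All derived results for one synthetic cohort."""

    table: pd.DataFrame                      # floored + control-scaled
    summary: pd.DataFrame
    comparisons: List[ComparisonResult]
    thresholds: Dict[str, TawssThresholds]   # per mouse (or {'pooled': ...})
    display_maxima: Dict[str, float]
    raw_maps: Dict[tuple, Dict[str, MetricMap]]         # (mouse, vessel) keys
    normalized_maps: Dict[tuple, Dict[str, MetricMap]]


def _vessel_base_maps(vd: VesselData) -> Dict[str, MetricMap]:
    adjacency = node_neighbors(vd.mesh)
    return compute_base_metrics(vd.field, vd.mesh.normals, adjacency)


def analyze_cohort(
    cohort: List[MouseDataset],
    floor: float = 0.005,
    threshold_mode: str = "per_mouse",
    threshold_multiplier: float = 0.67,
    ttest_mode: str = "unpaired",
) -> CohortAnalysis:
    """Metrics, thresholds, region table and statistics for a cohort."""
    if threshold_mode not in ("per_mouse", "pooled"):
        raise ValueError("threshold_mode must be 'per_mouse' or 'pooled'")

    raw: Dict[tuple, Dict[str, MetricMap]] = {}
    for ds in cohort:
        for vessel_name, vd in ds.vessels().items():
            try:
                raw[(ds.mouse_id, vessel_name)] = _vessel_base_maps(vd)
            except Exception as exc:
                raise RuntimeError(
                    f"metric stage failed for {ds.mouse_id}/{vessel_name}: {exc}"
                ) from exc

    # LSI/HSI thresholds from the contralateral control TAWSS
    thresholds: Dict[str, TawssThresholds] = {}
    if threshold_mode == "pooled":
        pooled_vals = np.concatenate(
            [raw[(ds.mouse_id, "control")]["TAWSS"].values for ds in cohort]
        )
        pooled = fit_thresholds(MetricMap("TAWSS", pooled_vals, "Pa"),
                                threshold_multiplier)
        thresholds["pooled"] = pooled
    for ds in cohort:
        thr = (thresholds["pooled"] if threshold_mode == "pooled"
               else fit_thresholds(raw[(ds.mouse_id, "control")]["TAWSS"],
                                   threshold_multiplier))
        thresholds.setdefault(ds.mouse_id, thr)
        for vessel_name in ("instrumented", "control"):
            maps = raw[(ds.mouse_id, vessel_name)]
            maps["LSI"] = lsi(maps["TAWSS"], thr)
            maps["HSI"] = hsi(maps["TAWSS"], thr)

    # cohort-observed display maxima for the unbounded metrics
    display_maxima: Dict[str, float] = {}
    for metric in OBSERVED_MAX_METRICS:
        finite = [m[metric].values[np.isfinite(m[metric].values)]
                  for m in raw.values()]
        display_maxima[metric] = float(
            max(v.max() for v in finite if v.size)
        )

    normalized: Dict[tuple, Dict[str, MetricMap]] = {}
    rows = []
    for ds in cohort:
        for vessel_name, vd in ds.vessels().items():
            maps = raw[(ds.mouse_id, vessel_name)]
            norm_maps = {
                name: normalize_display(m, display_maxima.get(name))
                for name, m in maps.items()
            }
            normalized[(ds.mouse_id, vessel_name)] = norm_maps
            for name, nm in norm_maps.items():
                for region, value in region_means(nm, vd.labels).items():
                    rows.append({
                        "mouse_id": ds.mouse_id,
                        "vessel": vessel_name,
                        "region": region,
                        "metric": name,
                        "mean_value": value,
                    })
    table = floor_and_scale(pd.DataFrame(rows), floor=floor)
    summary, comparisons = summarize_cohort(table,
                                            paired=(ttest_mode == "paired"))
    return CohortAnalysis(table=table, summary=summary,
                          comparisons=comparisons, thresholds=thresholds,
                          display_maxima=display_maxima, raw_maps=raw,
                          normalized_maps=normalized)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def field_to_frame(vd: VesselData) -> pd.DataFrame:
    n, k, _ = vd.field.vectors.shape
    node_id = np.repeat(np.arange(n), k)
    t_index = np.tile(np.arange(k), n)
    flat = vd.field.vectors.reshape(n * k, 3)
    return pd.DataFrame({
        "node_id": node_id,
        "t_index": t_index,
        "tau_x_Pa": flat[:, 0],
        "tau_y_Pa": flat[:, 1],
        "tau_z_Pa": flat[:, 2],
    })


def labels_to_frame(vd: VesselData) -> pd.DataFrame:
    return pd.DataFrame({
        "node_id": np.arange(vd.mesh.n_nodes),
        "s_mm": vd.frame.axial,
        "theta_rad": vd.frame.angular,
        "region": vd.labels.labels,
    })


def metric_maps_to_frame(vd: VesselData, maps: Dict[str, MetricMap]) -> pd.DataFrame:
    frames = []
    for name, m in maps.items():
        frames.append(pd.DataFrame({
            "node_id": np.arange(vd.mesh.n_nodes),
            "s_mm": vd.frame.axial,
            "theta_rad": vd.frame.angular,
            "metric": name,
            "value": m.values,
            "units": METRIC_UNITS.get(name, m.units),
        }))
    return pd.concat(frames, ignore_index=True)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_full_pipeline(config: PipelineConfig,
                      out_dir: Optional[str] = None) -> Path:
    """Simulate the cohort, compute everything and write the output tree.

    Returns the output directory.  Any stage failure aborts with the stage
    name and the offending mouse/vessel in the exception message.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "vessels").mkdir(exist_ok=True)

    try:
        cohort = synth_cohort(
            config.n_mice, config.instrumented, config.control,
            seed=config.master_seed, fluid=config.fluid,
            plaque_extent=config.plaque_extent_mm,
        )
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc

    analysis = analyze_cohort(
        cohort, floor=config.floor, threshold_mode=config.threshold_mode,
        threshold_multiplier=config.threshold_multiplier,
        ttest_mode=config.ttest_mode,
    )

    enface_frames = []
    for ds in cohort:
        for vessel_name, vd in ds.vessels().items():
            stem = out / "vessels" / f"{ds.mouse_id}_{vessel_name}"
            try:
                write_stl(vd.mesh, f"{stem}.stl")
                _write_csv(field_to_frame(vd), Path(f"{stem}_field.csv"))
                _write_csv(labels_to_frame(vd), Path(f"{stem}_regions.csv"))
                maps = analysis.raw_maps[(ds.mouse_id, vessel_name)]
                _write_csv(metric_maps_to_frame(vd, maps),
                           Path(f"{stem}_metrics.csv"))
                for name, nm in analysis.normalized_maps[
                        (ds.mouse_id, vessel_name)].items():
                    grid = enface(nm, vd.frame, config.n_s_bins,
                                  config.n_theta_bins)
                    gf = grid.to_frame()
                    gf.insert(0, "metric", name)
                    gf.insert(0, "vessel", vessel_name)
                    gf.insert(0, "mouse_id", ds.mouse_id)
                    enface_frames.append(gf)
            except Exception as exc:
                raise RuntimeError(
                    f"output stage failed for {ds.mouse_id}/{vessel_name}: {exc}"
                ) from exc

    _write_csv(pd.concat(enface_frames, ignore_index=True),
               out / "enface.csv")
    _write_csv(analysis.table, out / "region_metric_table.csv")
    _write_csv(analysis.summary, out / "comparisons_summary.csv")
    _write_csv(
        pd.DataFrame([vars(c) for c in analysis.comparisons]),
        out / "comparisons.csv",
    )

    thresholds_json = {
        mouse: {
            "low_Pa": thr.low,
            "high_Pa": thr.high,
            "mean_log": thr.source_mean_log,
            "sd_log": thr.source_sd_log,
            "source": config.threshold_mode,
        }
        for mouse, thr in analysis.thresholds.items()
    }
    (out / "thresholds.json").write_text(
        json.dumps(thresholds_json, indent=2, sort_keys=True), encoding="utf-8")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "mouse_seeds": {ds.mouse_id: ds.seed for ds in cohort},
        "display_maxima": analysis.display_maxima,
        "display_maxima_note": (
            "TAWSS, tSS and RRT are normalized by the cohort-observed "
            "maximum; OSI, SAD, LSI, HSI by their theoretical maxima."),
        "n_mice": config.n_mice,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    config.save(out / "config.yaml")
    logger.info("pipeline complete: %s", out)
    return out
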