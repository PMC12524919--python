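"""End-to-end pipeline: phantom -> quantify -> zones -> cohort -> stats.

A single YAML/JSON configuration drives every stage; all randomness flows from
the one global seed (stage seeds are spawned deterministically from it), so a
rerun with the same config reproduces byte-identical CSV/JSON artifacts.
Every run writes a manifest stamped with the config hash and seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import quantify, stats, zones
from .phantom import (
    CalcDeposit,
    CohortGenConfig,
    MetricFamily,
    PhantomConfig,
    ZONE_METRIC_COLUMNS,
    default_cohort_config,
    generate_cohort,
    generate_phantom,
)

__all__ = ["default_config", "validate_config", "run_pipeline"]

log = logging.getLogger("femcalc")


def default_config() -> dict:
    """The standard pipeline configuration (flat, namespaced sections)."""
    return {
        "seed": 0,
        "phantom": {
            "deposits": [
                {"shape": "sphere", "zone_label": "Z1", "peak_hu": 900.0,
                 "centerline_id": "cfa-dfa", "arc_mm": 12.0, "angle_deg": 40.0,
                 "radius_mm": 2.0, "label": "proximal-sphere"},
                {"shape": "arc-shell", "zone_label": "Z2", "peak_hu": 1100.0,
                 "centerline_id": "cfa-dfa", "arc_mm": 32.0, "angle_deg": 180.0,
                 "thickness_mm": 1.5, "angular_extent_deg": 120.0,
                 "length_mm": 6.0, "label": "distal-shell"},
                {"shape": "sphere", "zone_label": "Z3", "peak_hu": 1000.0,
                 "centerline_id": "cfa-sfa", "arc_mm": 50.0, "angle_deg": 0.0,
                 "radius_mm": 1.5, "label": "ostial-sphere"},
            ],
        },
        "quantify": {
            "sample_radius_mm": 1.5,
            "roi_radius_mm": 6.0,
            "delta_k": 2.0,
            "lumen_band_low_hu": 150.0,
            "min_component_mm3": 1.0,
            "operator_override_hu": None,
        },
        "cohort": {"n_limbs": 90},
        "stats": {
            "bootstrap_B": 1000,
            "bootstrap_ci": "bc",
            "psvr_cutoff": 2.4,
            "threshold_metric": "zone2_median_hu",
            # Azema type I is rare (~1 limb per 90), so the adjusted model uses
            # bifurcation involvement (type III vs I/II) instead of raw type
            "logistic_covariates": ["stent_type", "azema_iii"],
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    """Merge with defaults and check numeric parameters before any computation."""
    cfg = _merge(default_config(), cfg or {})
    q = cfg["quantify"]
    if q["delta_k"] < 0:
        raise ValueError(f"quantify.delta_k must be >= 0, got {q['delta_k']}")
    for key in ("sample_radius_mm", "roi_radius_mm"):
        if q[key] <= 0:
            raise ValueError(f"quantify.{key} must be positive")
    if q["min_component_mm3"] < 0:
        raise ValueError("quantify.min_component_mm3 must be >= 0")
    s = cfg["stats"]
    if s["bootstrap_B"] < 2:
        raise ValueError("stats.bootstrap_B must be >= 2")
    if s["psvr_cutoff"] <= 0:
        raise ValueError("stats.psvr_cutoff must be positive")
    if cfg["cohort"].get("n_limbs", 1) < 1:
        raise ValueError("cohort.n_limbs must be >= 1")
    return cfg


def _phantom_config(section: dict, seed: int) -> PhantomConfig:
    section = dict(section)
    deposits = [CalcDeposit(**d) for d in section.pop("deposits", [])]
    for tuple_key in ("grid_shape", "voxel_spacing", "trunk_start_mm"):
        if tuple_key in section:
            section[tuple_key] = tuple(section[tuple_key])
    return PhantomConfig(**section, deposits=deposits, seed=seed)


def _cohort_config(section: dict, seed: int) -> CohortGenConfig:
    section = dict(section)
    fam_override = section.pop("families", None)
    attrition = section.pop("attrition", True)
    cfg = default_cohort_config(seed=seed, attrition=attrition, **section)
    if fam_override:
        for grp, cols in fam_override.items():
            for col, params in cols.items():
                cfg.families[grp][col] = MetricFamily(
                    params["median"], params["q1"], params["q3"]
                )
    return cfg


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every stage in order, writing artifacts under ``out_dir``.

    Returns a small dict of headline results (threshold, AUC, patency rate).
    Any stage failure raises, halting downstream stages.
    """
    cfg = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    phantom_seed, cohort_seed, boot_seed = _stage_seeds(seed)

    # ---- phantom ---------------------------------------------------------
    pcfg = _phantom_config(cfg["phantom"], phantom_seed)
    volume, cset, landmarks, truth = generate_phantom(pcfg)
    fio.write_volume(volume, out / "phantom.nii.gz")
    fio.write_labelmap(truth.lumen_mask, truth.calc_mask, volume, out / "phantom_truth.nii.gz")
    fio.write_centerlines(cset, out / "centerlines.csv")
    fio.write_landmarks(landmarks, out / "landmarks.csv")
    log.info("phantom: %s voxels, %d deposits", volume.shape, len(pcfg.deposits))

    # ---- quantify --------------------------------------------------------
    q = cfg["quantify"]
    threshold = quantify.compute_detection_threshold(
        volume,
        list(cset),
        sample_radius_mm=q["sample_radius_mm"],
        delta_k=q["delta_k"],
        operator_override=q["operator_override_hu"],
    )
    rois = [quantify.build_tubular_roi(volume, line, q["roi_radius_mm"]) for line in cset]
    roi = quantify.merge_rois(rois)
    seg = quantify.segment_calcifications(
        volume,
        roi,
        threshold,
        lumen_band_low_hu=q["lumen_band_low_hu"],
        min_component_mm3=q["min_component_mm3"],
    )
    fio.write_labelmap(seg.lumen_mask, seg.calc_mask, volume, out / "segmentation.nii.gz")
    fio.dump_json(threshold.to_dict(), out / "threshold.json")

    # ---- zones -----------------------------------------------------------
    partition = zones.assign_zones(volume, roi.mask, cset, landmarks)
    metrics = zones.compute_zone_metrics(seg, partition, volume)
    metrics.to_csv(out / "zone_metrics.csv")
    counts = {z: int((partition.labels == z).sum()) for z in (1, 2, 3)}
    log.info(
        "audit volume=phantom threshold=%.1fHU zone_voxels=%s calc_mm3=%.1f",
        threshold.threshold_hu, counts, seg.calc_volume_mm3(volume),
    )

    # ---- cohort ----------------------------------------------------------
    ccfg = _cohort_config(cfg["cohort"], cohort_seed)
    cohort = generate_cohort(ccfg)
    fio.write_cohort(cohort, out / "cohort.csv")

    # ---- stats -----------------------------------------------------------
    s = cfg["stats"]
    cohort = stats.add_patency(cohort, cutoff=s["psvr_cutoff"])
    summary = stats.summarize_cohort(cohort, cutoff=s["psvr_cutoff"])
    evaluable = cohort[cohort["patency"].notna()]
    comparison = stats.compare_groups(
        evaluable, ZONE_METRIC_COLUMNS, group_col="patency",
        family="twelve-month zone metrics",
    )
    comparison.table.to_csv(out / "comparison_12m.csv", index=False)

    metric = s["threshold_metric"]
    roc = stats.roc_youden(evaluable[metric], evaluable["patency"], positive="restenosis")
    roc.curve.to_csv(out / "roc_curve.csv", index=False)
    boot = stats.bootstrap_threshold(
        evaluable[metric], evaluable["patency"], B=s["bootstrap_B"],
        seed=boot_seed, ci_method=s["bootstrap_ci"],
    )
    dense = evaluable[metric] >= roc.threshold
    lg_df = evaluable.assign(
        dense_calcification=dense.astype(int),
        restenosis_flag=(evaluable["patency"] == "restenosis").astype(int),
        azema_iii=(evaluable["azema"] == "III").astype(int),
    )
    logistic = stats.fit_logistic(
        lg_df, "restenosis_flag", ["dense_calcification"] + list(s["logistic_covariates"])
    )
    results = {
        "summary": summary,
        "roc": roc.to_dict(),
        "bootstrap": {
            "B": boot.B, "estimate_hu": boot.estimate,
            "ci": [boot.ci_low, boot.ci_high], "ci_method": boot.ci_method,
            "threshold_original_hu": boot.threshold_original,
            "n_redraws": boot.n_redraws,
        },
        "logistic": {
            "n": logistic.n,
            "terms": {
                t: {
                    "odds_ratio": float(r["odds_ratio"]),
                    "ci": [float(r["ci_low"]), float(r["ci_high"])],
                    "p_value": float(r["p_value"]),
                }
                for t, r in logistic.table.iterrows()
            },
        },
    }
    fio.dump_json(results, out / "stats.json")

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stage_seeds": {"phantom": phantom_seed, "cohort": cohort_seed, "bootstrap": boot_seed},
    }
    fio.dump_json(manifest, out / "manifest.json")
    return {
        "threshold_hu": threshold.threshold_hu,
        "youden_threshold_hu": roc.threshold,
        "auc": roc.auc,
        "patency_12m_pct": summary["patency_12m_pct"],
    }
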