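"""File formats: NIfTI volumes and label maps, CSV centerlines/landmarks/cohorts, YAML config.

Only axis-aligned acquisitions are supported: a NIfTI affine with rotation or
shear (oblique) terms is rejected rather than silently resampled.  Label maps
use the convention 0 = background, 1 = lumen, 2 = calcification.  Cohort CSVs
carry a schema-version header comment and unknown columns are preserved,
never dropped.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import Centerline, CenterlineSet, CTVolume, LandmarkSet
from .phantom import ZONE_METRIC_COLUMNS

__all__ = [
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_centerlines",
    "write_centerlines",
    "read_landmarks",
    "write_landmarks",
    "read_cohort",
    "write_cohort",
    "load_config",
    "COHORT_SCHEMA_VERSION",
    "COHORT_REQUIRED_COLUMNS",
]

COHORT_SCHEMA_VERSION = "femcalc-cohort v1"

COHORT_REQUIRED_COLUMNS = [
    "limb_id",
    "patient_id",
    "stent_type",
    "azema",
    "rutherford",
    "indication",
    "followup_status",
    "psvr_12m",
    "psvr_1m",
    "tlr_performed",
] + ZONE_METRIC_COLUMNS

_VALID_AZEMA = {"I", "II", "III"}


def _check_affine(affine: np.ndarray, path) -> tuple[tuple, tuple]:
    R = affine[:3, :3]
    off = R - np.diag(np.diag(R))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(R))):
        raise ValueError(
            f"'{path}': oblique affine is unsupported; only axis-aligned "
            "voxel-to-world scaling is handled"
        )
    diag = np.diag(R)
    if np.any(diag <= 0):
        raise ValueError(
            f"'{path}': negative or zero affine scaling (axis flips) is unsupported"
        )
    return tuple(float(d) for d in diag), tuple(float(t) for t in affine[:3, 3])


def read_volume(path) -> CTVolume:
    """Read a NIfTI-1 scalar volume; spacing and origin come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    spacing, origin = _check_affine(img.affine, path)
    values = np.asanyarray(img.dataobj)
    return CTVolume(values=values, spacing=spacing, origin=origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI-1; a write→read round trip is bit-exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labelmap(lumen_mask: np.ndarray, calc_mask: np.ndarray, volume: CTVolume, path) -> None:
    """Write the segmentation as an integer label map (0 bg, 1 lumen, 2 calc)."""
    labels = np.zeros(volume.shape, dtype=np.uint8)
    labels[np.asarray(lumen_mask, dtype=bool)] = 1
    labels[np.asarray(calc_mask, dtype=bool)] = 2
    write_volume(CTVolume(values=labels, spacing=volume.spacing, origin=volume.origin), path)


def read_labelmap(path) -> tuple[np.ndarray, np.ndarray, CTVolume]:
    """Read a label map back into (lumen_mask, calc_mask, carrier volume)."""
    vol = read_volume(path)
    labels = vol.values
    extra = set(np.unique(labels)) - {0, 1, 2}
    if extra:
        raise ValueError(f"'{path}': unexpected labels {sorted(extra)}; expected {{0, 1, 2}}")
    return labels == 1, labels == 2, vol


def write_centerlines(cset: CenterlineSet, path) -> None:
    rows = []
    for line in cset:
        for i, p in enumerate(line.points):
            rows.append(
                {
                    "centerline_id": line.id,
                    "point_index": i,
                    "x_mm": p[0],
                    "y_mm": p[1],
                    "z_mm": p[2],
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_centerlines(path) -> CenterlineSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"centerline file not found: {path}")
    df = pd.read_csv(path)
    required = {"centerline_id", "point_index", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"'{path}': missing centerline columns {sorted(missing)}")
    lines = []
    for cid, grp in df.groupby("centerline_id", sort=True):
        grp = grp.sort_values("point_index")
        lines.append(Centerline(str(cid), grp[["x_mm", "y_mm", "z_mm"]].to_numpy()))
    return CenterlineSet(lines)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(landmarks.as_records()).to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    df = pd.read_csv(path)
    required = {"name", "centerline_id", "arc_length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"'{path}': missing landmark columns {sorted(missing)}")
    by_name = df.set_index("name")
    try:
        return LandmarkSet(
            p2=by_name.loc["P2", "arc_length_mm"],
            p3=by_name.loc["P3", "arc_length_mm"],
            p4=by_name.loc["P4", "arc_length_mm"],
            p5=by_name.loc["P5", "arc_length_mm"],
            p6=by_name.loc["P6", "arc_length_mm"],
            dfa_id=str(by_name.loc["P5", "centerline_id"]),
            sfa_id=str(by_name.loc["P6", "centerline_id"]),
        )
    except KeyError as exc:
        raise ValueError(f"'{path}': landmark table must name P2..P6") from exc


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV with a schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema: {COHORT_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a limb-level cohort table.

    Missing density cells of calcification-free zones stay missing (NaN),
    never 0.  Azema type IV records are rejected (exclusion criterion), as are
    tables lacking required schema columns.  Unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"'{path}': cohort schema violation, missing columns {missing}")
    bad_azema = set(df["azema"].dropna().astype(str)) - _VALID_AZEMA
    if bad_azema:
        raise ValueError(
            f"'{path}': invalid Azema values {sorted(bad_azema)}; type IV lesions "
            "are excluded and only I/II/III are accepted"
        )
    if df["limb_id"].duplicated().any():
        dup = df.loc[df["limb_id"].duplicated(), "limb_id"].tolist()
        raise ValueError(f"'{path}': duplicate limb ids {dup}")
    df["psvr_12m"] = pd.to_numeric(df["psvr_12m"], errors="coerce")
    df["psvr_1m"] = pd.to_numeric(df["psvr_1m"], errors="coerce")
    df["tlr_performed"] = df["tlr_performed"].fillna(False).astype(bool)
    for col in ZONE_METRIC_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_config(path) -> dict:
    """Load a YAML (or JSON, being a YAML subset) configuration mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"'{path}': config must be a mapping")
    return cfg


def dump_json(obj, path) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
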