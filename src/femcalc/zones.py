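"""Landmark placement, three-zone partition of the femoral bifurcation, zone metrics.

The common femoral artery (CFA) and its bifurcation are divided into three
anatomical zones bounded by centerline landmarks:

* Zone 1, proximal CFA: arc interval [P2, P3) on the trunk;
* Zone 2, distal CFA: [P3, P4) on the trunk;
* Zone 3, bifurcation and ostial segments: [P4, P5) along the deep femoral
  (DFA) centerline united with [P4, P6) along the superficial femoral (SFA)
  centerline.

All intervals are half-open so that the zones are disjoint and exhaustive: a
voxel projecting to arc length exactly P3 belongs to Zone 2.  Each region-of-
interest voxel is projected onto its nearest centerline point (over both
centerlines); voxels equidistant to the two lines are assigned to the
lexicographically lower centerline id (the deep branch with the default
naming), so no voxel is ever counted twice.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Centerline, CenterlineSet, CTVolume, LandmarkSet

__all__ = ["ZonePartition", "place_landmarks", "assign_zones", "compute_zone_metrics"]

ZONES = (1, 2, 3)

#: columns of the per-zone metrics frame
METRIC_COLUMNS = [
    "calc_volume_mm3",
    "min_hu",
    "median_hu",
    "max_hu",
    "lumen_volume_mm3",
    "calc_lumen_ratio_pct",
]


def _shared_trunk_length(cset: CenterlineSet, step: float = 0.25) -> float:
    """Arc length up to which the two centerlines coincide (the bifurcation)."""
    a, b = cset.lines[0], cset.lines[1]
    pa, ta = a.resample(step)
    pb, _ = b.resample(step)
    m = min(len(pa), len(pb))
    same = np.linalg.norm(pa[:m] - pb[:m], axis=1) < 1e-6
    if not same[0]:
        raise ValueError("centerlines do not share a common trunk origin")
    k = int(np.argmin(same)) - 1 if not same.all() else m - 1
    return float(ta[k])


def place_landmarks(
    cset: CenterlineSet,
    epigastric_arc_mm: float = 5.0,
    distal_mm: float = 20.0,
    p4_arc: float | None = None,
    dfa_id: str | None = None,
    sfa_id: str | None = None,
) -> LandmarkSet:
    """Auto-place P2–P6 on a two-centerline bifurcation.

    P2 sits at the epigastric artery level (given as trunk arc length), P4 at
    the bifurcation (detected as the end of the shared trunk unless supplied),
    P3 midway between P2 and P4, and P5/P6 ``distal_mm`` (2 cm by default)
    beyond the ostia, measured along the vessel rather than as a Euclidean
    offset.
    """
    if len(cset) != 2:
        raise ValueError("landmark placement expects exactly two centerlines")
    if dfa_id is None:
        dfa_id = cset.ids[0]
    if sfa_id is None:
        sfa_id = next(i for i in cset.ids if i != dfa_id)
    p4 = _shared_trunk_length(cset) if p4_arc is None else float(p4_arc)
    p2 = float(epigastric_arc_mm)
    p3 = 0.5 * (p2 + p4)
    p5 = p4 + float(distal_mm)
    p6 = p4 + float(distal_mm)
    for cid, pend in ((dfa_id, p5), (sfa_id, p6)):
        if cset.get(cid).length + 1e-9 < pend:
            raise ValueError(
                f"centerline '{cid}' is too short to carry a landmark at {pend:.1f} mm"
            )
    return LandmarkSet(p2=p2, p3=p3, p4=p4, p5=p5, p6=p6, dfa_id=dfa_id, sfa_id=sfa_id)


@dataclass
class ZonePartition:
    """Zone labels for every grid voxel (0 = outside all zones / outside ROI)."""

    labels: np.ndarray
    landmarks: LandmarkSet
    intervals: dict[int, list[tuple[str, float, float]]]

    def zone_mask(self, zone: int) -> np.ndarray:
        return self.labels == zone


def assign_zones(
    volume: CTVolume,
    roi_mask: np.ndarray,
    cset: CenterlineSet,
    landmarks: LandmarkSet,
    step: float | None = None,
) -> ZonePartition:
    """Project ROI voxels onto the centerlines and label them with zones.

    Each voxel inherits the half-open arc interval of its nearest resampled
    centerline point.  Projections proximal to P2 or distal to P5/P6 stay
    unlabeled.  Ties between the two centerlines go to the deep branch.
    """
    dfa = cset.get(landmarks.dfa_id)
    sfa = cset.get(landmarks.sfa_id)
    gap = np.linalg.norm(dfa.point_at(landmarks.p4) - sfa.point_at(landmarks.p4))
    if gap > max(volume.spacing) + 1e-9:
        raise ValueError(
            "centerlines do not share a trunk point at the bifurcation P4 "
            f"(gap {gap:.3f} mm exceeds one voxel)"
        )
    if step is None:
        step = min(volume.spacing) / 2.0

    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != volume.shape:
        raise ValueError("ROI mask and volume grids differ in shape")
    idx = np.argwhere(roi_mask)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    intervals = {
        1: [(landmarks.dfa_id, landmarks.p2, landmarks.p3)],
        2: [(landmarks.dfa_id, landmarks.p3, landmarks.p4)],
        3: [
            (landmarks.dfa_id, landmarks.p4, landmarks.p5),
            (landmarks.sfa_id, landmarks.p4, landmarks.p6),
        ],
    }
    if len(idx) == 0:
        return ZonePartition(labels=labels, landmarks=landmarks, intervals=intervals)

    centers = volume.index_to_world(idx)
    dists, arcs = [], []
    for line in (dfa, sfa):
        pts, t = line.resample(step)
        d, j = cKDTree(pts).query(centers)
        dists.append(d)
        arcs.append(t[j])
    # strict inequality keeps equidistant voxels on the deep branch
    use_sfa = dists[1] < dists[0] - 1e-9
    arc = np.where(use_sfa, arcs[1], arcs[0])
    end = np.where(use_sfa, landmarks.p6, landmarks.p5)

    zone = np.zeros(len(idx), dtype=np.uint8)
    zone[(arc >= landmarks.p2) & (arc < landmarks.p3)] = 1
    zone[(arc >= landmarks.p3) & (arc < landmarks.p4)] = 2
    zone[(arc >= landmarks.p4) & (arc < end)] = 3
    labels[tuple(idx.T)] = zone
    return ZonePartition(labels=labels, landmarks=landmarks, intervals=intervals)


def compute_zone_metrics(segmentation, partition: ZonePartition, volume: CTVolume) -> pd.DataFrame:
    """Per-zone calcification volume, density order statistics and lumen ratio.

    Returns a frame indexed by zone with columns ``calc_volume_mm3``,
    ``min_hu``, ``median_hu``, ``max_hu``, ``lumen_volume_mm3`` and
    ``calc_lumen_ratio_pct``.  Density summaries are taken over calcified
    voxels only and are missing (NaN) for a zone without calcification; the
    volume of such a zone is 0.  A zone with no lumen voxels gets a missing
    ratio and a warning.
    """
    calc = np.asarray(segmentation.calc_mask, dtype=bool)
    lumen = np.asarray(segmentation.lumen_mask, dtype=bool)
    if calc.shape != volume.shape or partition.labels.shape != volume.shape:
        raise ValueError("masks and partition must be defined on the volume grid")
    vv = volume.voxel_volume_mm3
    rows = []
    for z in ZONES:
        zm = partition.labels == z
        cvox = volume.values[calc & zm]
        lumen_vol = float(np.count_nonzero(lumen & zm)) * vv
        calc_vol = float(cvox.size) * vv
        if cvox.size:
            dmin, dmed, dmax = float(cvox.min()), float(np.median(cvox)), float(cvox.max())
        else:
            dmin = dmed = dmax = np.nan
        if lumen_vol > 0:
            ratio = 100.0 * calc_vol / lumen_vol
        else:
            warnings.warn(f"zone {z} has no lumen voxels; ratio reported as missing")
            ratio = np.nan
        rows.append(
            {
                "zone": z,
                "calc_volume_mm3": calc_vol,
                "min_hu": dmin,
                "median_hu": dmed,
                "max_hu": dmax,
                "lumen_volume_mm3": lumen_vol,
                "calc_lumen_ratio_pct": ratio,
            }
        )
    return pd.DataFrame(rows).set_index("zone")
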