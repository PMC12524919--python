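"""Synthetic CT-angiography phantoms of the femoral bifurcation and simulated cohorts.

Two generators live here:

``generate_phantom`` rasterises a contrast-filled common femoral artery (CFA)
that splits into deep (DFA) and superficial (SFA) branches on an HU grid,
embeds calcium deposits of known geometry and density, and returns voxel-exact
ground truth, so the downstream segmentation and zone metrics can be checked
against analytic expectations.  Rasterisation is hard-edged by voxel-centre
membership; an optional Gaussian blur (off by default) softens edges.

``generate_cohort`` draws limb-level calcification metrics from log-normal
families parameterised by a target median and inter-quartile range, with
outcome-specific families per zone so that the patent/restenosis density
contrast seen at twelve-month duplex follow-up can be emulated at any sample
size.  Within a limb and zone the three density order statistics
(min/median/max) share one standard-normal draw (a comonotone coupling) and
are sorted, which preserves every marginal median while keeping rows
internally consistent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from scipy.stats import norm

from .core import Centerline, CenterlineSet, CTVolume, LandmarkSet
from .zones import place_landmarks

__all__ = [
    "CalcDeposit",
    "PhantomConfig",
    "PhantomGroundTruth",
    "MetricFamily",
    "CohortGenConfig",
    "generate_phantom",
    "generate_cohort",
    "default_cohort_config",
    "null_cohort_config",
    "theoretical_youden_threshold",
    "ZONE_METRIC_COLUMNS",
]

# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------


@dataclass
class CalcDeposit:
    """One calcium deposit with bookkeeping for the zone it was placed in.

    Spheres may be placed either at explicit world coordinates (``center_mm``)
    or on the vessel wall via ``(centerline_id, arc_mm, angle_deg)``.
    Arc-shells (partial rings hugging the wall) are always centerline-placed:
    they span ``angular_extent_deg`` around the wall at radius equal to the
    local vessel radius, with radial ``thickness_mm`` and axial ``length_mm``.
    """

    shape: str  # "sphere" | "arc-shell"
    zone_label: str  # "Z1" | "Z2" | "Z3"
    peak_hu: float
    center_mm: tuple[float, float, float] | None = None
    centerline_id: str | None = None
    arc_mm: float | None = None
    angle_deg: float = 0.0
    radius_mm: float | None = None
    thickness_mm: float | None = None
    angular_extent_deg: float | None = None
    length_mm: float = 5.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "arc-shell"):
            raise ValueError(f"unknown deposit shape '{self.shape}'")
        if self.zone_label not in ("Z1", "Z2", "Z3"):
            raise ValueError(f"unknown zone label '{self.zone_label}'")
        if self.shape == "sphere":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("sphere deposit needs radius_mm > 0")
            if self.center_mm is None and self.centerline_id is None:
                raise ValueError("sphere deposit needs center_mm or a centerline placement")
        else:
            if self.thickness_mm is None or self.thickness_mm <= 0:
                raise ValueError("arc-shell deposit needs thickness_mm > 0")
            if self.angular_extent_deg is None or not (0 < self.angular_extent_deg <= 360):
                raise ValueError("arc-shell deposit needs angular_extent_deg in (0, 360]")
            if self.centerline_id is None or self.arc_mm is None:
                raise ValueError("arc-shell deposit must be placed on a centerline")


@dataclass
class PhantomConfig:
    """Geometry, tissue HU values and noise of the synthetic bifurcation.

    Defaults give a 40 x 24 x 80 mm field of view at 0.5 mm isotropic voxels
    holding a 40 mm CFA trunk (radius 4 mm) that bifurcates at 30 degrees into
    a 30 mm deep branch (radius 2.5 mm) and superficial branch (radius 3 mm).
    Contrast-filled lumen sits at 300 HU over a 40 HU soft-tissue background
    with a 60 HU wall shell; additive Gaussian noise of 20 HU emulates a
    typical CTA noise floor while keeping dense deposits several hundred HU
    clear of it.
    """

    grid_shape: tuple[int, int, int] = (80, 48, 160)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    background_hu: float = 40.0
    lumen_hu: float = 300.0
    wall_hu: float = 60.0
    noise_sd: float = 20.0
    wall_thickness_mm: float = 1.5
    vessel_radii: dict = field(
        default_factory=lambda: {"cfa": 4.0, "dfa": 2.5, "sfa": 3.0}
    )
    bifurcation_angle_deg: float = 30.0
    trunk_start_mm: tuple[float, float, float] = (20.0, 12.0, 4.0)
    trunk_length_mm: float = 40.0
    daughter_length_mm: float = 30.0
    epigastric_arc_mm: float = 5.0
    smooth_sigma_mm: float = 0.0
    deposits: list[CalcDeposit] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 voxels along every axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lumen_hu <= self.background_hu:
            raise ValueError("lumen_hu must exceed background_hu (contrast filling)")
        if not 0 < self.bifurcation_angle_deg < 180:
            raise ValueError("bifurcation_angle_deg must lie in (0, 180)")
        for k in ("cfa", "dfa", "sfa"):
            if self.vessel_radii.get(k, 0) <= 0:
                raise ValueError(f"vessel radius '{k}' must be positive")
        for dep in self.deposits:
            if dep.peak_hu <= self.lumen_hu:
                raise ValueError(
                    f"deposit '{dep.label or dep.shape}' peak_hu must exceed lumen_hu"
                )


@dataclass
class PhantomGroundTruth:
    """Voxel-exact truth of a phantom: masks, per-zone volumes and densities."""

    calc_mask: np.ndarray
    lumen_mask: np.ndarray
    zone_volume_mm3: dict[int, float]
    zone_density_hu: dict[int, tuple[float, float, float] | None]
    deposit_voxels: list[np.ndarray]


def _make_centerlines(cfg: PhantomConfig) -> CenterlineSet:
    start = np.asarray(cfg.trunk_start_mm, dtype=float)
    axis = np.array([0.0, 0.0, 1.0])
    p4 = start + cfg.trunk_length_mm * axis
    half = math.radians(cfg.bifurcation_angle_deg) / 2.0
    d_dfa = np.array([-math.sin(half), 0.0, math.cos(half)])
    d_sfa = np.array([math.sin(half), 0.0, math.cos(half)])
    dfa = Centerline("cfa-dfa", np.stack([start, p4, p4 + cfg.daughter_length_mm * d_dfa]))
    sfa = Centerline("cfa-sfa", np.stack([start, p4, p4 + cfg.daughter_length_mm * d_sfa]))
    return CenterlineSet([dfa, sfa])


def _segment_tables(cfg: PhantomConfig, cset: CenterlineSet):
    """Constant-radius straight segments (trunk, deep, superficial)."""
    dfa, sfa = cset.get("cfa-dfa"), cset.get("cfa-sfa")
    trunk = dfa.points[:2]
    return [
        ("cfa", Centerline("_trunk", trunk), cfg.vessel_radii["cfa"]),
        ("dfa", Centerline("_dfa", dfa.points[1:]), cfg.vessel_radii["dfa"]),
        ("sfa", Centerline("_sfa", sfa.points[1:]), cfg.vessel_radii["sfa"]),
    ]


def _frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal frame perpendicular to ``tangent``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangent)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = ref - np.dot(ref, tangent) * tangent
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(tangent, n1)
    return n1, n2


def _vessel_radius_at(cfg: PhantomConfig, cid: str, arc: float) -> float:
    if arc < cfg.trunk_length_mm:
        return cfg.vessel_radii["cfa"]
    return cfg.vessel_radii["dfa"] if cid == "cfa-dfa" else cfg.vessel_radii["sfa"]


def _deposit_center(cfg: PhantomConfig, cset: CenterlineSet, dep: CalcDeposit) -> np.ndarray:
    if dep.center_mm is not None:
        return np.asarray(dep.center_mm, dtype=float)
    line = cset.get(dep.centerline_id)
    p = line.point_at(dep.arc_mm)
    t = line.tangent_at(dep.arc_mm)
    n1, n2 = _frame(t)
    r = _vessel_radius_at(cfg, dep.centerline_id, dep.arc_mm)
    th = math.radians(dep.angle_deg)
    return p + r * (math.cos(th) * n1 + math.sin(th) * n2)


def _check_inside(cfg: PhantomConfig, i: int, dep: CalcDeposit, center: np.ndarray, reach: float) -> None:
    sp = np.asarray(cfg.voxel_spacing)
    lo = -0.5 * sp
    hi = (np.asarray(cfg.grid_shape) - 0.5) * sp
    if np.any(center - reach < lo) or np.any(center + reach > hi):
        raise ValueError(
            f"deposit {i} ('{dep.label or dep.shape}') extends outside the grid"
        )


def _rasterize_deposit(
    cfg: PhantomConfig,
    cset: CenterlineSet,
    dep: CalcDeposit,
    i: int,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxel indices (K, 3) covered by one deposit (voxel-centre membership)."""
    sp = np.asarray(cfg.voxel_spacing)
    center = _deposit_center(cfg, cset, dep)
    if dep.shape == "sphere":
        reach = dep.radius_mm
    else:
        r_ves = _vessel_radius_at(cfg, dep.centerline_id, dep.arc_mm)
        reach = math.hypot(r_ves + dep.thickness_mm / 2.0, dep.length_mm / 2.0)
    _check_inside(cfg, i, dep, center, reach)

    lo = np.maximum(np.floor((center - reach) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center + reach) / sp).astype(int) + 1, np.asarray(shape))
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = idx * sp

    if dep.shape == "sphere":
        keep = np.sum((centers - center) ** 2, axis=1) <= dep.radius_mm**2
        return idx[keep]

    # arc-shell: cylindrical coordinates relative to the carrying centerline
    line = cset.get(dep.centerline_id)
    pts, t = line.resample(min(cfg.voxel_spacing) / 2.0)
    d, j = cKDTree(pts).query(centers)
    s = t[j]
    tangent = line.tangent_at(dep.arc_mm)
    n1, n2 = _frame(tangent)
    rel = centers - pts[j]
    ang = np.arctan2(rel @ n2, rel @ n1)
    dang = np.angle(np.exp(1j * (ang - math.radians(dep.angle_deg))))
    r_ves = _vessel_radius_at(cfg, dep.centerline_id, dep.arc_mm)
    keep = (
        (np.abs(s - dep.arc_mm) <= dep.length_mm / 2.0)
        & (np.abs(d - r_ves) <= dep.thickness_mm / 2.0)
        & (np.abs(dang) <= math.radians(dep.angular_extent_deg) / 2.0)
    )
    return idx[keep]


def generate_phantom(
    cfg: PhantomConfig,
) -> tuple[CTVolume, CenterlineSet, LandmarkSet, PhantomGroundTruth]:
    """Rasterise the bifurcation phantom; identical config+seed gives identical output."""
    cset = _make_centerlines(cfg)
    landmarks = place_landmarks(
        cset, epigastric_arc_mm=cfg.epigastric_arc_mm, p4_arc=cfg.trunk_length_mm
    )
    shape = tuple(cfg.grid_shape)
    sp = np.asarray(cfg.voxel_spacing)
    idx_grid = np.indices(shape).reshape(3, -1).T
    centers = idx_grid * sp

    step = min(cfg.voxel_spacing) / 2.0
    lumen = np.zeros(int(np.prod(shape)), dtype=bool)
    wall = np.zeros_like(lumen)
    for _, seg, radius in _segment_tables(cfg, cset):
        pts, _ = seg.resample(step)
        d, _ = cKDTree(pts).query(centers)
        lumen |= d <= radius
        wall |= d <= radius + cfg.wall_thickness_mm
    wall &= ~lumen
    lumen = lumen.reshape(shape)
    wall = wall.reshape(shape)

    clean = np.full(shape, cfg.background_hu, dtype=float)
    clean[wall] = cfg.wall_hu
    clean[lumen] = cfg.lumen_hu

    calc = np.zeros(shape, dtype=bool)
    deposit_voxels: list[np.ndarray] = []
    for i, dep in enumerate(cfg.deposits):
        vox = _rasterize_deposit(cfg, cset, dep, i, shape)
        deposit_voxels.append(vox)
        if len(vox):
            sel = tuple(vox.T)
            calc[sel] = True
            clean[sel] = np.maximum(clean[sel], dep.peak_hu)

    vv = float(np.prod(sp))
    zone_volume: dict[int, float] = {}
    zone_density: dict[int, tuple[float, float, float] | None] = {}
    for z, tag in ((1, "Z1"), (2, "Z2"), (3, "Z3")):
        zmask = np.zeros(shape, dtype=bool)
        for dep, vox in zip(cfg.deposits, deposit_voxels):
            if dep.zone_label == tag and len(vox):
                zmask[tuple(vox.T)] = True
        n = int(np.count_nonzero(zmask))
        zone_volume[z] = n * vv
        if n:
            vals = clean[zmask]
            zone_density[z] = (float(vals.min()), float(np.median(vals)), float(vals.max()))
        else:
            zone_density[z] = None

    if cfg.smooth_sigma_mm > 0:
        clean = ndimage.gaussian_filter(clean, sigma=cfg.smooth_sigma_mm / sp)

    rng = np.random.default_rng(cfg.seed)
    values = clean + rng.normal(0.0, cfg.noise_sd, shape) if cfg.noise_sd > 0 else clean.copy()

    truth = PhantomGroundTruth(
        calc_mask=calc,
        lumen_mask=lumen & ~calc,
        zone_volume_mm3=zone_volume,
        zone_density_hu=zone_density,
        deposit_voxels=deposit_voxels,
    )
    volume = CTVolume(values=values, spacing=tuple(cfg.voxel_spacing))
    return volume, cset, landmarks, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

_Z75 = norm.ppf(0.75)

#: per-zone metric columns of a limb record
ZONE_METRIC_COLUMNS = [
    f"zone{z}_{m}"
    for z in (1, 2, 3)
    for m in ("calc_volume_mm3", "min_hu", "median_hu", "max_hu", "calc_lumen_ratio_pct")
]


@dataclass(frozen=True)
class MetricFamily:
    """A log-normal family pinned to a target median and inter-quartile range.

    ``exp(mu) = median`` and ``sigma = ln(q3/q1) / (2 z_0.75)``, so the
    distribution's median and IQR equal the targets exactly.  The positive
    support and right skew match the spread of calcification volumes and
    densities in clinical cohorts.
    """

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        vals = (self.median, self.q1, self.q3)
        if not all(np.isfinite(vals)) or any(v <= 0 for v in vals):
            raise ValueError(f"metric family parameters must be finite and positive: {vals}")
        if not self.q1 < self.median < self.q3:
            raise ValueError(f"quartiles must bracket the median: {vals}")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.log(self.q3 / self.q1) / (2.0 * _Z75)

    def from_normal(self, z: np.ndarray) -> np.ndarray:
        return np.exp(self.mu + self.sigma * np.asarray(z))


# Outcome-stratified defaults for the twelve-month follow-up contrast:
# (median, q1, q3) of each zone metric in the restenosis (PSVR > 2.4) and
# patent groups of the emulated cohort.
_TWELVE_MONTH_FAMILIES: dict[str, dict[str, tuple[float, float, float]]] = {
    "restenosis": {
        "zone1_calc_volume_mm3": (121, 75, 238),
        "zone1_min_hu": (561, 431, 712),
        "zone1_median_hu": (888, 748, 1124),
        "zone1_max_hu": (1650, 1261, 2092),
        "zone1_calc_lumen_ratio_pct": (12.1, 6.25, 17.1),
        "zone2_calc_volume_mm3": (190, 86, 335),
        "zone2_min_hu": (652, 522, 833),
        "zone2_median_hu": (858, 788, 987),
        "zone2_max_hu": (1911, 1364, 2008),
        "zone2_calc_lumen_ratio_pct": (15.2, 8.7, 21.7),
        "zone3_calc_volume_mm3": (48, 8, 100),
        "zone3_min_hu": (527, 412, 640),
        "zone3_median_hu": (748, 538, 932),
        "zone3_max_hu": (1202, 824, 1582),
        "zone3_calc_lumen_ratio_pct": (6.41, 0.915, 11.4),
    },
    "patent": {
        "zone1_calc_volume_mm3": (234, 72, 428),
        "zone1_min_hu": (588, 452, 708),
        "zone1_median_hu": (998, 836, 1142),
        "zone1_max_hu": (1812, 1469, 1982),
        "zone1_calc_lumen_ratio_pct": (19.1, 8.14, 28.1),
        "zone2_calc_volume_mm3": (282, 142, 494),
        "zone2_min_hu": (627, 537, 723),
        "zone2_median_hu": (1122, 903, 1248),
        "zone2_max_hu": (1907, 1682, 2181),
        "zone2_calc_lumen_ratio_pct": (20.4, 13.2, 27.6),
        "zone3_calc_volume_mm3": (80, 30, 148),
        "zone3_min_hu": (648, 537, 752),
        "zone3_median_hu": (999, 821, 1132),
        "zone3_max_hu": (1631, 1296, 1955),
        "zone3_calc_lumen_ratio_pct": (8.86, 3.82, 13.8),
    },
}


@dataclass
class CohortGenConfig:
    """Sampling plan for a synthetic limb-level cohort.

    ``families`` maps outcome group -> zone metric column -> MetricFamily.
    Structural covariate frequencies default to a femoral-bifurcation stenting
    population: mostly balloon-expandable stents, Azema II/III lesions and
    claudication as the dominant indication, with ~23% restenosis among
    followed limbs and small attrition (death / loss to follow-up).
    """

    n_limbs: int = 90
    restenosis_prob: float = 19 / 84
    families: dict[str, dict[str, MetricFamily]] = field(default_factory=dict)
    death_prob: float = 3 / 90
    lost_prob: float = 3 / 90
    missing_1m_prob: float = 1 / 90
    tlr_prob_restenosis: float = 0.15
    balloon_expandable_prob: float = 64 / 90
    azema_probs: tuple[float, float, float] = (1 / 90, 39 / 90, 50 / 90)
    rutherford_probs: tuple[float, ...] = (3 / 90, 25 / 90, 43 / 90, 7 / 90, 10 / 90, 2 / 90)
    bilateral_prob: float = 0.09
    psvr_cutoff: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_limbs < 1:
            raise ValueError("n_limbs must be >= 1")
        if not 0 < self.restenosis_prob < 1:
            raise ValueError("restenosis_prob must lie strictly between 0 and 1")
        for p in (self.death_prob, self.lost_prob, self.missing_1m_prob,
                  self.tlr_prob_restenosis, self.balloon_expandable_prob,
                  self.bilateral_prob):
            if not 0 <= p <= 1 or not np.isfinite(p):
                raise ValueError("probabilities must be finite and within [0, 1]")
        if abs(sum(self.azema_probs) - 1) > 1e-9 or abs(sum(self.rutherford_probs) - 1) > 1e-9:
            raise ValueError("categorical probabilities must sum to 1")


def default_cohort_config(
    n_limbs: int = 90, seed: int = 0, attrition: bool = True, **overrides
) -> CohortGenConfig:
    """The standard outcome-stratified cohort: zone-wise density/volume families
    with the patent group denser in the distal CFA than the restenosis group.

    ``attrition=False`` zeroes death/loss/missing probabilities, yielding a
    fully evaluable analysis cohort.
    """
    families = {
        grp: {col: MetricFamily(*params) for col, params in cols.items()}
        for grp, cols in _TWELVE_MONTH_FAMILIES.items()
    }
    cfg = CohortGenConfig(n_limbs=n_limbs, seed=seed, families=families, **overrides)
    if not attrition:
        cfg = replace(cfg, death_prob=0.0, lost_prob=0.0, missing_1m_prob=0.0)
    return cfg


def null_cohort_config(n_limbs: int = 90, seed: int = 0, **overrides) -> CohortGenConfig:
    """A zero-effect cohort: both outcome groups share the patent families."""
    cfg = default_cohort_config(n_limbs=n_limbs, seed=seed, **overrides)
    cfg.families = {grp: dict(cfg.families["patent"]) for grp in ("patent", "restenosis")}
    return cfg


_DENSITY_STATS = ("min_hu", "median_hu", "max_hu")


def generate_cohort(cfg: CohortGenConfig) -> pd.DataFrame:
    """Draw a limb-level cohort table; identical config+seed gives identical tables.

    Columns follow the cohort schema: identifiers, covariates, follow-up
    status, PSVR at one and twelve months, a TLR flag, the generator's true
    outcome label, and the fifteen per-zone calcification metrics.
    """
    if not cfg.families.get("patent") or not cfg.families.get("restenosis"):
        raise ValueError("cohort config needs metric families for both outcome groups")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_limbs

    restenosis = rng.random(n) < cfg.restenosis_prob
    u_status = rng.random(n)
    status = np.where(
        u_status < cfg.death_prob,
        "died",
        np.where(u_status < cfg.death_prob + cfg.lost_prob, "lost", "followed"),
    )
    stent = np.where(
        rng.random(n) < cfg.balloon_expandable_prob,
        "balloon-expandable",
        "self-expandable",
    )
    azema = rng.choice(np.array(["I", "II", "III"]), size=n, p=cfg.azema_probs)
    rutherford = rng.choice(np.arange(1, 7), size=n, p=cfg.rutherford_probs)
    indication = np.where(rutherford <= 3, "claudication", "CLTI")

    tlr = restenosis & (rng.random(n) < cfg.tlr_prob_restenosis)
    psvr_low = rng.uniform(0.8, 2.3, n)
    psvr_high = rng.uniform(2.5, 6.0, n)
    psvr_12m = np.where(restenosis & ~tlr, psvr_high, psvr_low)
    followed = status == "followed"
    psvr_12m = np.where(followed, psvr_12m, np.nan)
    tlr = tlr & followed

    v1 = rng.uniform(0.8, 2.3, n)
    v1_high = rng.uniform(2.5, 4.0, n)
    psvr_1m = np.where(rng.random(n) < 0.1, v1_high, v1)
    psvr_1m = np.where(rng.random(n) < cfg.missing_1m_prob, np.nan, psvr_1m)

    data: dict[str, np.ndarray] = {}
    for z in (1, 2, 3):
        z_dens = rng.standard_normal(n)
        trio = np.empty((n, 3))
        for j, stat in enumerate(_DENSITY_STATS):
            col = f"zone{z}_{stat}"
            mu = np.where(
                restenosis,
                cfg.families["restenosis"][col].mu,
                cfg.families["patent"][col].mu,
            )
            sig = np.where(
                restenosis,
                cfg.families["restenosis"][col].sigma,
                cfg.families["patent"][col].sigma,
            )
            trio[:, j] = np.exp(mu + sig * z_dens)
        trio.sort(axis=1)
        for j, stat in enumerate(_DENSITY_STATS):
            data[f"zone{z}_{stat}"] = trio[:, j]
        for stat in ("calc_volume_mm3", "calc_lumen_ratio_pct"):
            col = f"zone{z}_{stat}"
            zz = rng.standard_normal(n)
            mu = np.where(
                restenosis,
                cfg.families["restenosis"][col].mu,
                cfg.families["patent"][col].mu,
            )
            sig = np.where(
                restenosis,
                cfg.families["restenosis"][col].sigma,
                cfg.families["patent"][col].sigma,
            )
            data[col] = np.exp(mu + sig * zz)

    # one patient can own both limbs of one procedure (never more than two)
    patient_ids: list[str] = []
    pid = 0
    prev_shared = True
    share = rng.random(n) < cfg.bilateral_prob
    for i in range(n):
        if i > 0 and share[i] and not prev_shared:
            patient_ids.append(patient_ids[-1])
            prev_shared = True
        else:
            patient_ids.append(f"PT{pid:04d}")
            pid += 1
            prev_shared = False

    df = pd.DataFrame(
        {
            "limb_id": [f"L{i:04d}" for i in range(n)],
            "patient_id": patient_ids,
            "stent_type": stent,
            "azema": azema,
            "rutherford": rutherford,
            "indication": indication,
            "followup_status": status,
            "psvr_12m": psvr_12m,
            "psvr_1m": psvr_1m,
            "tlr_performed": tlr,
            "true_outcome": np.where(restenosis, "restenosis", "patent"),
        }
    )
    for col in ZONE_METRIC_COLUMNS:
        df[col] = data[col]
    return df


def study_flow_cohort() -> pd.DataFrame:
    """Deterministic 90-limb table reproducing the reported patient flow of the
    emulated femoral-stenting cohort: 3 deaths and 3 losses to follow-up, 19 of
    84 followed limbs with PSVR above the patency cut-off, one limb lacking the
    one-month duplex, and the Rutherford / Azema / stent-type marginals.

    Marginal columns are assigned positionally and independently; only the
    marginal counts (not their joint distribution) are meaningful.  Zone
    metrics are left missing: this table exercises cohort arithmetic, not the
    imaging chain.
    """
    n = 90
    status = ["died"] * 3 + ["lost"] * 3 + ["followed"] * 84
    psvr_12m = [np.nan] * 6 + [3.0] * 19 + [1.5] * 65
    psvr_1m = [np.nan] + [1.2] * 89
    rutherford = [1] * 3 + [2] * 25 + [3] * 43 + [4] * 7 + [5] * 10 + [6] * 2
    df = pd.DataFrame(
        {
            "limb_id": [f"L{i:04d}" for i in range(n)],
            "patient_id": [f"PT{i:04d}" for i in range(n)],
            "stent_type": ["balloon-expandable"] * 64 + ["self-expandable"] * 26,
            "azema": ["I"] * 1 + ["II"] * 39 + ["III"] * 50,
            "rutherford": rutherford,
            "indication": ["claudication" if r <= 3 else "CLTI" for r in rutherford],
            "followup_status": status,
            "psvr_12m": psvr_12m,
            "psvr_1m": psvr_1m,
            "tlr_performed": [False] * n,
        }
    )
    for col in ZONE_METRIC_COLUMNS:
        df[col] = np.nan
    return df


def theoretical_youden_threshold(
    cfg: CohortGenConfig, column: str = "zone2_median_hu"
) -> float:
    """The generating separation point of one metric: the HU value where the two
    groups' log-normal densities cross between their medians, i.e. the
    population maximiser of (sensitivity + specificity - 1) for a threshold
    rule on that metric."""
    fp = cfg.families["patent"][column]
    fr = cfg.families["restenosis"][column]
    mup, sp_ = fp.mu, fp.sigma
    mur, sr = fr.mu, fr.sigma
    lo, hi = min(mup, mur), max(mup, mur)
    if abs(sp_ - sr) < 1e-12:
        return math.exp(0.5 * (mup + mur))
    A = 1.0 / (2 * sp_**2) - 1.0 / (2 * sr**2)
    B = mur / sr**2 - mup / sp_**2
    C = mup**2 / (2 * sp_**2) - mur**2 / (2 * sr**2) + math.log(sp_) - math.log(sr)
    roots = np.roots([A, B, C])
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = real[(real > lo) & (real < hi)]
    y = float(inside[0]) if len(inside) else float(0.5 * (mup + mur))
    return math.exp(y)
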