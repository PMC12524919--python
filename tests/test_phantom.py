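"""Phantom rasterisation and cohort-generator behaviour."""
import numpy as np
import pandas as pd
import pytest

from femcalc.phantom import (
    CalcDeposit,
    CohortGenConfig,
    MetricFamily,
    PhantomConfig,
    default_cohort_config,
    generate_cohort,
    generate_phantom,
    null_cohort_config,
    theoretical_youden_threshold,
)
from femcalc.stats import wilcoxon_rank_sum

from conftest import small_phantom_config


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

def test_no_deposits_means_zero_calcification_everywhere():
    cfg = small_phantom_config(deposits=[])
    _, _, _, truth = generate_phantom(cfg)
    assert not truth.calc_mask.any()
    assert truth.zone_volume_mm3 == {1: 0.0, 2: 0.0, 3: 0.0}
    assert all(v is None for v in truth.zone_density_hu.values())
    assert truth.lumen_mask.sum() > 0


@pytest.mark.parametrize("spacing", [1.0, 0.5])
def test_sphere_volume_matches_brute_force_rasterizer(spacing):
    """Hard-edged rasterisation equals an independent full-grid voxel-centre
    scan, and the volume is within one voxel-shell of the analytic sphere."""
    radius, center = 3.0, np.array([12.3, 8.1, 30.2])
    cfg = small_phantom_config(
        deposits=[
            CalcDeposit(shape="sphere", zone_label="Z2", peak_hu=1000.0,
                        center_mm=tuple(center), radius_mm=radius, label="ball")
        ]
    )
    shape = tuple(int(round(n * 0.5 / spacing)) for n in cfg.grid_shape)
    cfg.grid_shape, cfg.voxel_spacing = shape, (spacing,) * 3
    _, _, _, truth = generate_phantom(cfg)

    # oracle: exhaustive voxel-centre-in-sphere test over the whole grid
    ii, jj, kk = np.indices(shape)
    centers = np.stack([ii, jj, kk], axis=-1) * spacing
    oracle = np.sum((centers - center) ** 2, axis=-1) <= radius**2
    assert np.array_equal(truth.calc_mask, oracle)

    analytic = 4.0 / 3.0 * np.pi * radius**3
    shell = 4.0 * np.pi * radius**2 * spacing  # one voxel-shell worth of volume
    measured = truth.calc_mask.sum() * spacing**3
    assert abs(measured - analytic) <= shell


def test_rasterization_error_shrinks_with_resolution():
    """Mean |rasterised - analytic| volume over several sub-voxel sphere
    placements decreases when the grid is refined (a single placement can be
    accidentally exact at the coarse resolution, so the check averages)."""
    radius = 3.0
    analytic = 4.0 / 3.0 * np.pi * radius**3
    rng = np.random.default_rng(8)
    offsets = rng.uniform(-0.6, 0.6, size=(6, 3))
    mean_errors = []
    for spacing in (1.0, 0.5):
        errs = []
        for off in offsets:
            center = np.array([12.3, 8.1, 30.2]) + off
            cfg = small_phantom_config(
                deposits=[
                    CalcDeposit(shape="sphere", zone_label="Z2", peak_hu=1000.0,
                                center_mm=tuple(center), radius_mm=radius)
                ]
            )
            shape = tuple(int(round(n * 0.5 / spacing)) for n in cfg.grid_shape)
            cfg.grid_shape, cfg.voxel_spacing = shape, (spacing,) * 3
            _, _, _, truth = generate_phantom(cfg)
            errs.append(abs(truth.calc_mask.sum() * spacing**3 - analytic))
        mean_errors.append(np.mean(errs))
    assert mean_errors[1] < mean_errors[0]


def test_phantom_seed_determinism():
    cfg = small_phantom_config(noise_sd=20.0, seed=7)
    v1, _, _, t1 = generate_phantom(cfg)
    v2, _, _, t2 = generate_phantom(small_phantom_config(noise_sd=20.0, seed=7))
    assert np.array_equal(v1.values, v2.values)
    assert np.array_equal(t1.calc_mask, t2.calc_mask)


def test_truth_masks_disjoint_and_zone_bookkeeping_consistent(clean_phantom):
    _, _, _, truth = clean_phantom
    assert not (truth.calc_mask & truth.lumen_mask).any()
    vv = 0.5**3
    assert sum(truth.zone_volume_mm3.values()) == pytest.approx(
        truth.calc_mask.sum() * vv
    )
    for stats_ in truth.zone_density_hu.values():
        if stats_ is not None:
            lo, med, hi = stats_
            assert lo <= med <= hi


def test_deposit_outside_grid_raises_with_name():
    cfg_kwargs = dict(small_phantom_config().__dict__)
    cfg_kwargs.pop("deposits")
    dep = CalcDeposit(shape="sphere", zone_label="Z1", peak_hu=900.0,
                      center_mm=(2.0, 2.0, 2.0), radius_mm=5.0, label="runaway")
    cfg = PhantomConfig(**cfg_kwargs, deposits=[dep])
    with pytest.raises(ValueError, match="runaway"):
        generate_phantom(cfg)


def test_phantom_landmarks_follow_auto_placement_rules(clean_phantom):
    _, _, lm, _ = clean_phantom
    assert lm.p2 == 4.0 and lm.p4 == 28.0
    assert lm.p3 == pytest.approx(0.5 * (lm.p2 + lm.p4))
    assert lm.p5 == pytest.approx(lm.p4 + 20.0)
    assert lm.p6 == pytest.approx(lm.p4 + 20.0)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def test_cohort_marginal_medians_hit_targets_at_large_n():
    """Sample medians converge to their configured targets.

    Density families are tight (log-scale SD ~ 0.2), so 2% holds at n = 5000;
    the volume families are an order of magnitude more dispersed (log-scale
    SD ~ 1), so their check uses three standard errors of the sample median,
    whichever is wider.
    """
    cfg = default_cohort_config(n_limbs=5000, seed=5, attrition=False)
    df = generate_cohort(cfg)
    for grp in ("patent", "restenosis"):
        sub = df[df["true_outcome"] == grp]
        for col in ("zone2_median_hu", "zone1_median_hu", "zone3_median_hu",
                    "zone2_calc_volume_mm3", "zone2_calc_lumen_ratio_pct"):
            fam = cfg.families[grp][col]
            # relative SE of a log-normal sample median
            se = np.sqrt(np.pi / 2) * fam.sigma / np.sqrt(len(sub))
            tol = max(0.02, 3 * se)
            assert sub[col].median() == pytest.approx(fam.median, rel=tol), (grp, col)


def test_cohort_density_order_statistics_are_ordered():
    df = generate_cohort(default_cohort_config(n_limbs=2000, seed=3))
    for z in (1, 2, 3):
        assert (df[f"zone{z}_min_hu"] <= df[f"zone{z}_median_hu"]).all()
        assert (df[f"zone{z}_median_hu"] <= df[f"zone{z}_max_hu"]).all()


def test_null_effect_cohort_shows_no_group_difference():
    df = generate_cohort(null_cohort_config(n_limbs=2000, seed=17, attrition=False))
    a = df.loc[df["true_outcome"] == "patent", "zone2_median_hu"]
    b = df.loc[df["true_outcome"] == "restenosis", "zone2_median_hu"]
    p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
    assert p > 0.01
    assert a.median() == pytest.approx(b.median(), rel=0.05)


def test_cohort_seed_determinism():
    a = generate_cohort(default_cohort_config(n_limbs=10, seed=4))
    b = generate_cohort(default_cohort_config(n_limbs=10, seed=4))
    pd.testing.assert_frame_equal(a, b)


def test_invalid_generator_parameters_rejected():
    with pytest.raises(ValueError):
        MetricFamily(median=-5.0, q1=1.0, q3=2.0)
    with pytest.raises(ValueError):
        MetricFamily(median=float("nan"), q1=1.0, q3=2.0)
    with pytest.raises(ValueError):
        CohortGenConfig(restenosis_prob=0.0)


def test_theoretical_separation_point_lies_between_group_medians():
    cfg = default_cohort_config()
    t = theoretical_youden_threshold(cfg, "zone2_median_hu")
    lo = cfg.families["restenosis"]["zone2_median_hu"].median
    hi = cfg.families["patent"]["zone2_median_hu"].median
    assert lo < t < hi
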