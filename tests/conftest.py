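import numpy as np
import pytest

from femcalc.core import CTVolume
from femcalc.phantom import CalcDeposit, PhantomConfig, generate_phantom


def small_phantom_config(noise_sd: float = 0.0, seed: int = 11, deposits=None) -> PhantomConfig:
    """A compact bifurcation phantom (24 x 16 x 58 mm FOV) with one deposit per zone."""
    if deposits is None:
        deposits = [
            CalcDeposit(
                shape="sphere", zone_label="Z1", peak_hu=900.0,
                centerline_id="cfa-dfa", arc_mm=8.0, angle_deg=30.0,
                radius_mm=1.5, label="z1-sphere",
            ),
            CalcDeposit(
                shape="arc-shell", zone_label="Z2", peak_hu=1100.0,
                centerline_id="cfa-dfa", arc_mm=22.0, angle_deg=180.0,
                thickness_mm=1.5, angular_extent_deg=100.0, length_mm=4.0,
                label="z2-shell",
            ),
            CalcDeposit(
                shape="sphere", zone_label="Z3", peak_hu=1000.0,
                centerline_id="cfa-sfa", arc_mm=34.0, angle_deg=0.0,
                radius_mm=1.2, label="z3-sphere",
            ),
        ]
    return PhantomConfig(
        grid_shape=(48, 32, 116),
        voxel_spacing=(0.5, 0.5, 0.5),
        trunk_start_mm=(12.0, 8.0, 4.0),
        trunk_length_mm=28.0,
        daughter_length_mm=24.0,
        epigastric_arc_mm=4.0,
        noise_sd=noise_sd,
        seed=seed,
        deposits=deposits,
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: (volume, centerlines, landmarks, ground truth)."""
    return generate_phantom(small_phantom_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with a 20 HU Gaussian noise floor."""
    return generate_phantom(small_phantom_config(noise_sd=20.0, seed=13))


@pytest.fixture()
def constant_volume():
    return CTVolume(values=np.full((21, 21, 21), 300.0), spacing=(1.0, 1.0, 1.0))
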