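import warnings

import numpy as np
import pytest

from nanoruler.geometry import default_geometry
from nanoruler.simulate import (LabelingParams, NoiseParams,
                                simulate_particle, standing_pose)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


def make_standing_clouds(geometry, n, seed, site_params=None, tilt_sd=5.0,
                         labeling=None, noise=None):
    """Standing-particle localization clouds in the lab frame."""
    rng = np.random.default_rng(seed)
    labeling = labeling or LabelingParams()
    noise = noise or NoiseParams()
    out = []
    for _ in range(n):
        R = standing_pose(rng, tilt_sd)
        tab, _ = simulate_particle(geometry, labeling, noise, rng,
                                   rotation=R, translation=np.zeros(3),
                                   site_params=site_params)
        out.append(tab[["x_nm", "y_nm", "z_nm"]].to_numpy())
    return out


@pytest.fixture(scope="session")
def standing_clouds(geometry):
    """30 standing particles at the default study conditions."""
    return make_standing_clouds(geometry, 30, seed=101)


@pytest.fixture(scope="session")
def dense_tail_clouds(geometry):
    """30 standing particles with densely labelled tails."""
    return make_standing_clouds(
        geometry, 30, seed=102,
        site_params={"tail_density_per_nm2": 0.03})
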