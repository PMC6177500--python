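import numpy as np
import pytest

from wallmap.synthetic import (
    CohortConfig,
    generate_bifurcation_mesh,
    generate_cohort,
    generate_velocity_image,
)


@pytest.fixture(scope="session")
def straight_tube():
    """Straight cylinder lumen, radius 3 mm, length 15 mm, with branch specs."""
    mesh, branches = generate_bifurcation_mesh(
        radii={"cca": 3.0}, lengths={"cca": 15.0}, pitch=0.5, return_branches=True
    )
    return mesh, branches


@pytest.fixture(scope="session")
def bifurcation():
    """Default carotid-like bifurcation mesh with branch specs."""
    return generate_bifurcation_mesh(seed=1, return_branches=True)


@pytest.fixture(scope="session")
def tube_velocity(straight_tube):
    """Noise-free parabolic velocity volume for the straight tube."""
    mesh, branches = straight_tube
    img = generate_velocity_image(
        mesh, peak_velocity=60.0, voxel_mm=(0.5, 0.5, 0.5), branches=branches
    )
    return img


@pytest.fixture(scope="session")
def small_cohort():
    """Four noiseless synthetic subjects (maps only, no velocity volumes)."""
    cfg = CohortConfig(n_subjects=4, noise_sd=0.0, seed=11)
    return generate_cohort(cfg, with_velocity=False)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Six subjects under the default noise conditions (maps only)."""
    cfg = CohortConfig(n_subjects=6, noise_sd=0.2, seed=12)
    return generate_cohort(cfg, with_velocity=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
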