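"""Shared fixtures: compact phantoms and planning contexts.

Heavy objects (influence matrices, the cohort experiment) are session
scoped; the "small" geometry uses a reduced head so unit tests stay fast
while exercising the same code paths as the full-size study."""

import numpy as np
import pytest

from shellplan.phantom import PhantomSpec, generate_phantom
from shellplan.transfer import ExperimentConfig, build_patient_context

SMALL_HEAD = (50.0, 55.0, 50.0)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(head_radii_mm=SMALL_HEAD, voxel_mm=4.0,
                       ptv_volume_cc=2.9, ptv_brainstem_gap_mm=1.0,
                       rng_seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(node_count=60, n_collimators=2,
                            n_random_aim_points=1, voxel_mm=4.0)


@pytest.fixture(scope="session")
def small_context(small_phantom, small_config):
    return build_patient_context(small_phantom, small_config, aim_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
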