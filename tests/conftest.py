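import warnings

import numpy as np
import pytest
import trimesh

from heartatlas import AtlasParams, CohortConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_geometry_warnings():
    """Keep expected degenerate-structure warnings from cluttering output."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20211220)


def rotated(mesh: trimesh.Trimesh, angle: float, axis, shift) -> trimesh.Trimesh:
    out = mesh.copy()
    out.apply_transform(trimesh.transformations.rotation_matrix(angle, axis))
    out.apply_translation(shift)
    return out


@pytest.fixture(scope="session")
def smoke_config():
    """Small, fast cohort configuration used by pipeline/CLI tests."""
    return CohortConfig(
        n_patients=2,
        n_observers=3,
        master_seed=7,
        atlas=AtlasParams(grid_spacing=2.5),
    )


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory, smoke_config):
    path = tmp_path_factory.mktemp("cohort") / "dataset"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        generate_cohort(smoke_config, path)
    return path
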