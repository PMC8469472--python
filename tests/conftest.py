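import dataclasses

import numpy as np
import pytest

from ado.mesh_io import write_surface
from ado.pipeline import PipelineConfig, run_pipeline
from ado.surface_analysis import estimate_curvature
from ado.synthetic import BicuspidSpec, generate_bicuspid, icosphere


@pytest.fixture(scope="session")
def default_fixture():
    """Default-resolution bicuspid (the acceptance fixture)."""
    return generate_bicuspid()


@pytest.fixture(scope="session")
def coarse_spec():
    return dataclasses.replace(BicuspidSpec(), resolution=0.5)


@pytest.fixture(scope="session")
def coarse_fixture(coarse_spec):
    """Cheaper fixture for property tests that re-run the pipeline stages."""
    return generate_bicuspid(coarse_spec)


@pytest.fixture(scope="session")
def shell_field(default_fixture):
    return estimate_curvature(default_fixture.shell)


@pytest.fixture(scope="session")
def coarse_shell_field(coarse_fixture):
    return estimate_curvature(coarse_fixture.shell)


@pytest.fixture(scope="session")
def shell_path(default_fixture, tmp_path_factory):
    path = tmp_path_factory.mktemp("mesh") / "shell.ply"
    write_surface(default_fixture.shell, path)
    return path


@pytest.fixture(scope="session")
def pipeline_result(default_fixture, shell_path, tmp_path_factory):
    """One full default pipeline run, shared across the suite."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(output_dir=str(outdir))
    return run_pipeline(config, shell_path)


@pytest.fixture(scope="session")
def unit_sphere():
    return icosphere(1.0, 4)


@pytest.fixture(scope="session")
def unit_sphere_coarse():
    return icosphere(1.0, 3)


@pytest.fixture
def toy_contour():
    """Closed symmetric two-cusp polygon: tips (+-4, 10), valley (0, 6)."""
    return np.array(
        [
            [-7.0, 0.0], [-6.5, 6.0], [-4.0, 10.0], [-2.0, 7.8], [0.0, 6.0],
            [2.0, 7.8], [4.0, 10.0], [6.5, 6.0], [7.0, 0.0], [3.0, -2.0],
            [0.0, -2.5], [-3.0, -2.0],
        ]
    )
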