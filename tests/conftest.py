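"""Shared fixtures.

The expensive fixtures are session-scoped: one healthy disaccommodation run
on the coarse mesh, and the full 90-scenario pseudoexfoliation sweep used
by the trend and comparison tests.
"""

import numpy as np
import pytest

from phakosim import (
    BoundaryProtocol,
    GeometryParams,
    LensModel,
    RunConfig,
    build_complex,
    build_lens_profile,
    generate_mesh,
    run_study,
)
from phakosim.optics import compute_metrics
from phakosim.study import build_base_mesh


@pytest.fixture(scope="session")
def smoke_config():
    return RunConfig(mesh_preset="smoke")


@pytest.fixture(scope="session")
def smoke_mesh(smoke_config):
    return build_base_mesh(smoke_config)


@pytest.fixture(scope="session")
def healthy_run(smoke_mesh):
    """Healthy base model (Oval+5.6, Band4, gravity) solved on the coarse mesh."""
    model = LensModel(smoke_mesh, protocol=BoundaryProtocol(gravity=True))
    result = model.solve()
    record = compute_metrics(model, result)
    return model, result, record


@pytest.fixture(scope="session")
def initial_mesh():
    """Non-oval zero-width-ring variant (the axisymmetric reference model)."""
    profile = build_lens_profile()
    complex_ = build_complex(profile, GeometryParams.from_variants("Initial", "Ring"))
    return generate_mesh(complex_, target_edge_length=1.7, n_theta=24)


@pytest.fixture(scope="session")
def sweep_table(smoke_config, tmp_path_factory):
    """Metrics table of the healthy baseline plus all 90 zonulopathy models."""
    out = tmp_path_factory.mktemp("sweep")
    return run_study(smoke_config, out_dir=out)
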