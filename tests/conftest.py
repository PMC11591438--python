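"""Shared fixtures: expensive flow solves are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from microtrench.fixtures import make_fixture
from microtrench.flow import solve_steady_flow
from microtrench.meshing import generate_mesh
from microtrench.wss import coverage_objective, wall_shear_stress


def solve_fixture(name: str, resolution: str):
    cfg = make_fixture(name)
    mesh = generate_mesh(cfg.design, cfg.channel, resolution)
    flow = solve_steady_flow(mesh, cfg.fluid, cfg.flow, tol=cfg.tol,
                             max_iter=cfg.max_iter)
    return cfg, mesh, flow


@pytest.fixture(scope="session")
def frendl_flow():
    """Vertical 700x400 um trenches at 600 dyn/cm^2 bulk (coarse mesh)."""
    return solve_fixture("frendl-vertical", "coarse")


@pytest.fixture(scope="session")
def frendl_wss(frendl_flow):
    _, _, flow = frendl_flow
    return wall_shear_stress(flow)


@pytest.fixture(scope="session")
def pilot_coverages():
    """Coverage objective of the pilot trio (theta = 60/90/120) at the
    default coarse resolution."""
    out = {}
    for theta in (60, 90, 120):
        cfg, mesh, flow = solve_fixture(f"pilot-theta{theta}", "coarse")
        out[theta] = coverage_objective(wall_shear_stress(flow),
                                        cfg.thresholds).f
    return out

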