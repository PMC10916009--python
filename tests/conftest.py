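"""Shared fixtures and factories for the test suite."""

import numpy as np
import pytest

from coa_surrogate.geometry import (
    AortaGeometry,
    BranchSpec,
    FlowBC,
    straight_centerline,
)
from coa_surrogate.oracle import OracleConfig, solve_case


def make_tube(
    length=100.0,
    radius=10.0,
    spacing=2.0,
    case_id="tube",
    branches=(),
    severity=0.0,
    stenosis_center=None,
    stenosis_width=6,
):
    """Straight-tube geometry, optionally with a Gaussian stenosis."""
    from coa_surrogate.geometry import make_radius_profile

    pts = straight_centerline(length, spacing)
    n = len(pts)
    if severity > 0:
        center = n // 2 if stenosis_center is None else stenosis_center
        r = make_radius_profile(n, radius, severity, center, stenosis_width)
    else:
        r = np.full(n, float(radius))
    return AortaGeometry(
        case_id=case_id,
        centerline_points=pts,
        spacing=spacing,
        radius=r,
        branches=list(branches),
    )


@pytest.fixture
def tube_factory():
    return make_tube


@pytest.fixture
def flow_bc():
    return FlowBC(inlet_flow=300e-6)  # 300 ml/s


@pytest.fixture
def stenotic_solved(flow_bc):
    """A solved straight stenotic case (severity 0.4)."""
    geom = make_tube(length=160.0, severity=0.4, case_id="sten")
    return geom, flow_bc, solve_case(geom, flow_bc)


@pytest.fixture(scope="session")
def small_cohort_solved():
    """Six solved synthetic cases from the standard generator."""
    from coa_surrogate.geometry import sample_cohort

    cohort = sample_cohort(6, seed=3)
    return [(g, bc, solve_case(g, bc)) for g, bc in cohort]
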