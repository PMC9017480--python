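"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from ahflow.fixtures import SpeckleParams, render_oct_image
from ahflow.geometry import AnteriorSegmentSpec, NodeGrid, NodeType, build_parametric_domain
from ahflow.lb import FluidProperties


@pytest.fixture(scope="session")
def default_spec():
    return AnteriorSegmentSpec()


@pytest.fixture(scope="session")
def default_props():
    return FluidProperties()


@pytest.fixture(scope="session")
def oct_fixture(default_spec):
    """Speckled OCT-like rendering with ground truth, fixed seed."""
    return render_oct_image(
        default_spec, pixel_size=0.05, speckle=SpeckleParams(looks=4, seed=7)
    )


@pytest.fixture(scope="session")
def coarse_grid(default_spec):
    """The cheapest usable eye lattice (dx = 0.125 mm)."""
    return build_parametric_domain(default_spec, 0.125)


def closed_box_grid(n=16, m=None):
    """A closed rectangular cavity: fluid surrounded by walls, no inlet/outlet."""
    m = m or n
    labels = np.full((n + 2, m + 2), int(NodeType.WALL_IRIS), dtype=np.int8)
    labels[1:-1, 1:-1] = NodeType.FLUID
    return NodeGrid(labels=labels, dx=1.0)
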