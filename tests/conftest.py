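"""Shared fixtures: coarse, fast problem instances for the slow solvers."""

from __future__ import annotations

import pytest

from mpsbarrier import geometry as G
from mpsbarrier import twophase as tp


#: coarse grid spacing for two-phase runs in tests [m]
COARSE_DX = 5e-6
#: single pillar period domain width [m]
COARSE_WIDTH = 87.5e-6


@pytest.fixture(scope="session")
def straight_domain():
    return tp.build_burst_domain("straight", dx=COARSE_DX, width=COARSE_WIDTH)


@pytest.fixture(scope="session")
def pillar_domain():
    return tp.build_burst_domain("pillar", dx=COARSE_DX, width=COARSE_WIDTH)


@pytest.fixture(scope="session")
def small_device():
    """Two-pillar-period device for transport tests (same physics, ~4× faster)."""
    spec = G.PillarArraySpec.from_layout(
        n_pillars=2,
        pore_size=8e-6,
        pillar_height=2e-6,
        strip_length=2 * 79.5e-6 + 3 * 8e-6,
        strip_depth=125e-6,
    )
    return G.DeviceGeometry(
        chamber_width=300e-6,
        chamber_height=150e-6,
        chamber_length=spec.strip_length,
        media_channel_width=100e-6,
        media_channel_height=150e-6,
        barrier=spec,
    )
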