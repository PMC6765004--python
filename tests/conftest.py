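"""Shared fixtures: the default array/medium/pulse and the expensive
simulation products reused across test modules (session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from uslr import (
    Medium,
    SectorGeometry,
    USLRParams,
    das_beamform,
    focus_delays,
    hamming_scheme,
    lateral_profile_of_scheme,
    make_array,
    optimize_uslr,
    single_wire,
    sweep_sector,
)
from uslr.array_model import emitted_pulse


@pytest.fixture(scope="session")
def array():
    return make_array()            # 128 el, 0.22 mm pitch, 3 MHz


@pytest.fixture(scope="session")
def medium():
    return Medium()                # 1540 m/s, no attenuation


@pytest.fixture(scope="session")
def pulse():
    return emitted_pulse(3.0)


@pytest.fixture(scope="session")
def single_profile_60(array, medium, pulse):
    """Lateral transmit profile of the unapodized single focus at 60 mm."""
    scheme = focus_delays(array, (0.0, 60.0), medium)
    return lateral_profile_of_scheme(array, scheme, pulse, 60.0, medium)


@pytest.fixture(scope="session")
def hamming_profile_60(array, medium, pulse):
    scheme = hamming_scheme(array, (0.0, 60.0), medium)
    return lateral_profile_of_scheme(array, scheme, pulse, 60.0, medium)


@pytest.fixture(scope="session")
def optimization_60(array, medium, pulse):
    """Default-grid (c, delta_x) optimization at the 60 mm focal depth."""
    return optimize_uslr(array, 60.0, medium=medium, pulse=pulse)


@pytest.fixture(scope="session")
def params_70(array, medium, pulse):
    """Depth-scaled optimization at 70 mm (see optimize_for_depth)."""
    from uslr import optimize_for_depth
    return optimize_for_depth(array, 70.0, medium, pulse)


@pytest.fixture(scope="session")
def wire_images(array, medium, pulse):
    """Sector B-mode images of a 60 mm wire: single-focus vs interlaced."""
    wire = single_wire(60.0)
    geom = SectorGeometry(n_angles=128, field_of_view=18.0, focal_depth=60.0,
                          depth_range=(50.0, 70.0))
    out = {}
    for kind, params in [("single", None), ("uslr", USLRParams(0.37, 3.0))]:
        cds = sweep_sector(array, wire, geom, medium, pulse, kind=kind,
                           params=params)
        out[kind] = das_beamform(cds, array, geom, medium, pulse)
    return out
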