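"""Shared fixtures.

The directional-protocol simulations are the expensive part of the
suite, so every DSResult that more than one test needs is computed once
per session.  Protocol fixtures run at dt = 0.05 ms; the engine's
step-size convergence test demonstrates that halving dt changes summed
peaks by far less than any tolerance asserted here.
"""

from __future__ import annotations

import numpy as np
import pytest

from rgcds.engine import CellModel, Simulation
from rgcds.channels import ChannelDistribution, standard_channels, calibrate_hcn_offset
from rgcds.morphology import Region, build_soma_only
from rgcds.protocols import (
    DirectionalProtocol,
    PROXIMAL_SITE_DISTANCES,
    build_standard_cell,
    run_direction_pair,
    run_voltage_step_family,
)

PROTOCOL_DT = 0.05  # ms


def _pair(model, *, include_singles=False, sites=None):
    proto = DirectionalProtocol(
        sites=sites or tuple(s for s, _ in model.synapses), dt=PROTOCOL_DT
    )
    return run_direction_pair(model, proto, include_singles=include_singles)


@pytest.fixture(scope="session")
def standard_results():
    """DSResult per channel configuration of the standard cell."""
    out = {}
    for cs in ("full", "passive", "hcn", "nak"):
        out[cs] = _pair(
            build_standard_cell(channel_set=cs), include_singles=(cs == "full")
        )
    return out


@pytest.fixture(scope="session")
def proximal_result():
    """Full model activated only at proximal (<100 um) sites."""
    model = build_standard_cell(site_distances=PROXIMAL_SITE_DISTANCES)
    return _pair(model)


@pytest.fixture(scope="session")
def hcn_patch_cell():
    """Isopotential HCN-expressing compartment for voltage-clamp work."""
    dist = ChannelDistribution(densities={"HCN": {Region.SOMA: 0.005}})
    offset = calibrate_hcn_offset(0.25, -65.0)
    return CellModel(
        build_soma_only(), dist, standard_channels(hcn_offset=offset), []
    )


@pytest.fixture(scope="session")
def iv_family(hcn_patch_cell):
    return run_voltage_step_family(
        hcn_patch_cell, steps=tuple(range(-100, -35, 5))
    )


@pytest.fixture(scope="session")
def equilibrated_standard():
    """An equilibrated simulation of the full standard model."""
    sim = Simulation(build_standard_cell(), dt=PROTOCOL_DT)
    sim.equilibrate(dt=1.0)
    return sim
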