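"""Shared fixtures for the oxzhydro test suite."""

from __future__ import annotations

import numpy as np
import pytest

from oxzhydro import model as mdl
from oxzhydro import thermo


@pytest.fixture(scope="session")
def default_air():
    """Air state at the shipped default leaf temperature and VPD."""
    return thermo.air_state_from_vpd(3.8, mdl.T_LEAF_DEFAULT)


@pytest.fixture(scope="session")
def small_network():
    """A coarse network for fast solver-behavior tests."""
    net = mdl.DEFAULT_NETWORK
    return mdl.LeafNetwork(n_layers=11, thickness=net.thickness,
                           xylem_position=net.xylem_position,
                           k_cc=net.k_cc, k_vap=net.k_vap, a_int=net.a_int)


@pytest.fixture(scope="session")
def steep_law():
    """A sigmoid with its midpoint well below zero, so kappa(0) ~ kappa_max."""
    return mdl.MembraneLaw(kappa_max=1e-3, kappa_min=1e-5,
                           psi_50=-1.0, slope=0.15)


def random_network(rng: np.random.Generator) -> mdl.LeafNetwork:
    """A random but physically sensible network for property tests."""
    return mdl.LeafNetwork(
        n_layers=int(rng.integers(1, 30)),
        thickness=float(rng.uniform(1e-4, 5e-4)),
        xylem_position=float(rng.uniform(0.2, 0.8)),
        k_cc=float(10 ** rng.uniform(-6, -4)),
        k_vap=float(10 ** rng.uniform(-7, -5)),
        a_int=float(10 ** rng.uniform(4, 6)),
    )


def random_law(rng: np.random.Generator) -> mdl.MembraneLaw:
    k_min = float(10 ** rng.uniform(-6, -4))
    return mdl.MembraneLaw(
        kappa_max=k_min * float(10 ** rng.uniform(0.5, 2.5)),
        kappa_min=k_min,
        psi_50=float(rng.uniform(-1.5, -0.05)),
        slope=float(rng.uniform(0.05, 0.5)),
    )
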