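"""Shared fixtures: expensive Monte Carlo artifacts are session-scoped."""

import numpy as np
import pytest

from ludose.mc import SimulationConfig, generate_vsv
from ludose.nuclide import load_lu177
from ludose.phantom import build_phantom, cohort_sampler


@pytest.fixture(scope="session")
def lu177():
    return load_lu177()


@pytest.fixture(scope="session")
def soft_kernel_small(lu177):
    """Soft-tissue VSV kernel on a reduced 31^3 grid for convolution tests."""
    cfg = SimulationConfig(n_primaries=300_000, seed=42)
    return generate_vsv("soft_tissue_icrp", lu177, cfg, grid_n=31)


@pytest.fixture(scope="session")
def small_phantom():
    """A 3-lesion phantom truth on the default 48^3 grid."""
    spec = cohort_sampler(3, seed=7)
    return build_phantom(spec)
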