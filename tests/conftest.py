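"""Shared fixtures: synthetic metadynamics runs reused across test modules."""

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from mdfes import default_spec, simulate
from mdfes.hills_io import CVMeta, Hills


@pytest.fixture(scope="session")
def dw_run():
    """Default well-tempered double-well run (the converged 1D fixture)."""
    spec = default_spec("double_well_1d", seed=1)
    hills, traj = simulate(spec)
    return spec, hills, traj


@pytest.fixture(scope="session")
def fw_run_small():
    """A short 2D four-well run for cheap multi-dimensional tests."""
    spec = default_spec("four_well_2d", seed=2, n_steps=5_000)
    hills, traj = simulate(spec)
    return spec, hills, traj


@pytest.fixture
def simple_hills():
    """Three hand-written 1D hills on a non-periodic CV."""
    return Hills(
        times=[1.0, 2.0, 3.0],
        centers=[[-0.5], [0.0], [0.4]],
        widths=[[0.2], [0.2], [0.2]],
        heights=[1.0, 0.8, 1.2],
        cv_meta=(CVMeta("d1"),),
    )


@pytest.fixture
def periodic_hills():
    """Two hills on a periodic CV spanning the wrap point."""
    meta = (CVMeta("phi", periodic=True, period_lo=-np.pi, period_hi=np.pi),)
    return Hills(
        times=[1.0, 2.0],
        centers=[[-np.pi + 0.01], [1.0]],
        widths=[[0.3], [0.3]],
        heights=[1.0, 1.0],
        cv_meta=meta,
    )
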