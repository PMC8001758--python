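"""Shared fixtures.

The two well-tempered-metadynamics benchmark runs are expensive (tens of
seconds to minutes), so they are session-scoped and shared between the
engine tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from bilayerlab.toy_system import BilayerSpec, generate_bilayer, ground_truth_fes
from bilayerlab.trajectory_io import CVMeta, CVSeries, HillLog, Trajectory
from bilayerlab.wtm_engine import (
    default_grid,
    double_well_study,
    four_basin_study,
    reconstruct_fes,
    run_wtm,
)


@pytest.fixture(scope="session")
def wtm_1d():
    """Shipped 1D double-well benchmark run: (spec, cfg, series, hills, grid, truth)."""
    spec, cfg = double_well_study()
    series, hills = run_wtm(spec, cfg)
    grid = default_grid(spec.potential, cfg)
    truth = ground_truth_fes(spec, grid)
    return spec, cfg, series, hills, grid, truth


@pytest.fixture(scope="session")
def wtm_1d_fes(wtm_1d):
    spec, cfg, series, hills, grid, truth = wtm_1d
    return reconstruct_fes(hills, grid)


@pytest.fixture(scope="session")
def wtm_2d():
    """Shipped 2D four-basin benchmark run: (spec, cfg, series, hills, grid, truth)."""
    spec, cfg = four_basin_study()
    series, hills = run_wtm(spec, cfg)
    grid = default_grid(spec.potential, cfg)
    truth = ground_truth_fes(spec, grid)
    return spec, cfg, series, hills, grid, truth


@pytest.fixture()
def flat_bilayer():
    """Jitter-free reference bilayer: spacing 0.78 nm, separation 4.0 nm."""
    spec = BilayerSpec(
        n_lipids_per_leaflet=100,
        lattice_spacing=0.78,
        leaflet_separation=4.0,
        positional_jitter_sd=0.0,
        box_fluctuation_sd=0.0,
        n_frames=5,
        seed=0,
        probe_z=3.0,
    )
    return generate_bilayer(spec)


@pytest.fixture()
def small_trajectory():
    """Tiny hand-made 2-frame, 3-particle trajectory."""
    return Trajectory(
        times=np.array([0.0, 1.0]),
        coords=np.array(
            [
                [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.5, 0.5, 0.5]],
                [[1.1, 2.1, 3.1], [4.1, 5.1, 6.1], [0.6, 0.6, 0.6]],
            ]
        ),
        box=np.array([[8.0, 8.0, 8.1], [8.0, 8.0, 8.1]]),
        labels=["P", "P", "PRB"],
        groups={"P": np.array([0, 1]), "probe": np.array([2])},
    )


@pytest.fixture()
def three_hills():
    return HillLog(
        deposit_times=np.array([1.0, 2.0, 3.0]),
        centers=np.array([[0.5, 10.0], [1.0, -170.0], [-0.5, 179.0]]),
        widths=np.tile([0.3, 20.0], (3, 1)),
        heights=np.array([1.0, 0.9, 0.8]),
        bias_factor=10.0,
        cv_meta=[
            CVMeta("z", "nm"),
            CVMeta("psi", "degrees", periodic=True, period=360.0),
        ],
    )


@pytest.fixture()
def psi_series():
    return CVSeries(
        times=np.arange(5.0),
        values=np.array([[0.1, 10.0], [0.2, 20.0], [0.3, 30.0], [0.4, 40.0], [0.5, 50.0]]),
        cv_meta=[
            CVMeta("z", "nm"),
            CVMeta("psi", "degrees", periodic=True, period=360.0),
        ],
    )
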