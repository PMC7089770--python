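"""Shared fixtures: small seeded synthetic datasets reused across tests."""

import numpy as np
import pytest

from rodspt import (CellSimConfig, MotionSimConfig, PopulationSimConfig,
                    generate_synthetic_cell, simulate_bound_motion_tracks,
                    simulate_tracked_population)


@pytest.fixture(scope="session")
def immobile_tracks():
    """Pure-immobile bound-molecule tracks under calibration conditions."""
    return simulate_bound_motion_tracks(MotionSimConfig(
        n_tracks=4000, k_ip=0.0, k_pi=0.0, initial_state="immobile", seed=11))


@pytest.fixture(scope="session")
def persistent_tracks():
    """Pure-persistent tracks at 14 nm/s under calibration conditions."""
    return simulate_bound_motion_tracks(MotionSimConfig(
        n_tracks=4000, k_ip=0.0, k_pi=0.0, initial_state="persistent",
        direction="x", seed=12))


@pytest.fixture(scope="session")
def mixture_tracks():
    """Bound/diffusive population at the reference condition (b=0.22, D=0.042)."""
    return simulate_tracked_population(PopulationSimConfig(
        b=0.22, d_states=((0.78, 0.042),), sigma_loc=0.025, tau=0.06,
        n_tracks=8000, mean_steps=10, seed=13))


@pytest.fixture(scope="session")
def bent_cell():
    """Uniformly bent noise-free cell with intensity-curvature coupling."""
    cfg = CellSimConfig(length=10.0, width=1.0, kappa=0.2, alpha=0.2, seed=7)
    return generate_synthetic_cell(cfg)


@pytest.fixture(scope="session")
def straight_cell():
    cfg = CellSimConfig(length=10.0, width=1.0, kappa=0.0, alpha=0.2, seed=7)
    return generate_synthetic_cell(cfg)


def mixed_bend_cells(n_cells=16, seed=100, noise=0.02, bulges=True):
    """Cells with straight and bent stretches plus curvature-neutral bulges.

    The cubed-sine bend profile keeps roughly half of each cell's arclength
    below the straight-segment threshold while the bent stretches reach
    0.25-0.35 1/um, so both the straight-mask analysis and the bending
    corrections have signal to work with.
    """
    out = []
    for k in range(n_cells):
        amp = 0.25 + 0.05 * (k % 3)
        cfg = CellSimConfig(
            length=12.0, width=1.0,
            kappa=lambda s, a=amp: a * np.sin(2 * np.pi * s / 12.0) ** 3,
            alpha=0.2, intensity_noise=noise,
            bulge_amplitude=0.06 if bulges else 0.0,
            n_bulges=6 if bulges else 0, seed=seed + k)
        out.append(generate_synthetic_cell(cfg))
    return out
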