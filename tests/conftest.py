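"""Shared fixtures: default model setups and small synthetic panels."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import zoometals as zm


@pytest.fixture(scope="session")
def params() -> zm.EcosystemParams:
    return zm.EcosystemParams()


@pytest.fixture(scope="session")
def forcing() -> zm.Forcing:
    return zm.Forcing()


@pytest.fixture(scope="session")
def short_trajectory(params, forcing):
    """Two model years of the default configuration (shared, read-only)."""
    return zm.run(params, forcing, t_end=2 * 365.0, dt=0.25)


@pytest.fixture(scope="session")
def attractor_state(params, forcing):
    """State vector on the seasonal attractor of the default configuration."""
    spin = zm.run(params, forcing, t_end=10 * 365.0, dt=0.25, save_every_days=365.0)
    return zm.ecosystem.trajectory_state_vector(spin, -1)


@pytest.fixture(scope="session")
def closed_box_params(params) -> zm.EcosystemParams:
    """No mixing, no sinking, no external sources: conserved inventories."""
    return dataclasses.replace(
        params,
        kappa0=0.0,
        lam_sink=0.0,
        s_n=0.0,
        s_m={e: 0.0 for e in zm.ELEMENTS},
    )


@pytest.fixture(scope="session")
def synthetic_panel():
    """A mid-size panel with known ground truth (R^2 = 0.6)."""
    spec = zm.PanelSpec(n_per_region=2000, target_r2=0.6, seed=42,
                        coefficients=(2.0, -1.0, 0.5, 1.5))
    panel, truth = zm.generate_driver_panel(spec)
    return spec, panel, truth


def random_panel(seed: int, n: int = 80):
    """Small random panel for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((4, 4))
    cov = a @ a.T + 0.5 * np.eye(4)
    spec = zm.PanelSpec(
        n_per_region=n,
        regions=[zm.RegionSpec("R0", rng.normal(size=4), cov)],
        coefficients=tuple(rng.normal(size=4)),
        target_r2=float(rng.uniform(0.3, 0.9)),
        seed=seed,
    )
    panel, _ = zm.generate_driver_panel(spec)
    return panel
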