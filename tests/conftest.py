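"""Shared fixtures and oracles: rendered beads, sweeps, brute-force grid."""

from __future__ import annotations

import numpy as np
import pytest

from refplane.profile import ProfileParams, select_lam, _knots, _scatter, _solve
from refplane.synth import OpticalModel, SweepSpec, render_bead, simulate_sweep


@pytest.fixture(scope="session")
def optical_model() -> OpticalModel:
    return OpticalModel()


@pytest.fixture(scope="session")
def quiet_model() -> OpticalModel:
    """Noise-free variant of the default optical model."""
    from dataclasses import replace

    return replace(OpticalModel(), noise_sd=0.0)


@pytest.fixture(scope="session")
def focus_tile(optical_model) -> np.ndarray:
    """One in-focus bead tile at the tile midpoint, with noise."""
    return render_bead(0.0, 9.0, optical_model, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def lam(focus_tile) -> float:
    """Dataset smoothing parameter, selected once per session."""
    return select_lam(focus_tile, (31.5, 31.5), ProfileParams().center_max_radius)


@pytest.fixture(scope="session")
def small_sweep(optical_model):
    """A compact noisy sweep: 9 Z levels, 2 exposures, 1 FOV, 6 beads."""
    spec = SweepSpec(
        z_min=1477.5, z_max=1537.5, z_increment=7.5, exposures=(6.0, 9.0),
        n_fov=1, beads_per_fov=6, true_refp=1507.5, seed=42,
    )
    images, manifest = simulate_sweep(spec, optical_model)
    return spec, images, manifest


def grid_argmin(tile, lam, init, radius=16.0):
    """Brute-force grid oracle: coarse 0.25 px pass, then 0.05 px refinement."""
    tile = np.asarray(tile, float)
    t = _knots(radius)

    def sse(c):
        r, v = _scatter(tile, c, radius)
        return _solve(r, v, lam, t)[1]

    best = min(
        ((sse((init[0] + dx, init[1] + dy)), (init[0] + dx, init[1] + dy))
         for dx in np.arange(-2, 2.001, 0.25) for dy in np.arange(-2, 2.001, 0.25)),
    )[1]
    best = min(
        ((sse((best[0] + dx, best[1] + dy)), (best[0] + dx, best[1] + dy))
         for dx in np.arange(-0.3, 0.301, 0.05) for dy in np.arange(-0.3, 0.301, 0.05)),
    )[1]
    return best


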