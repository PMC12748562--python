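"""Shared fixtures: small, fast simulated scenes used across the suite.

The workhorse scene is three equal point sources on one plane 30 um
behind a strongly scattering screen on a 64 x 64 grid — small enough
that retrieval, demixing and reconstruction all run in seconds, while
exercising exactly the same physics as the full-size geometries.
"""

from __future__ import annotations

import numpy as np
import pytest

from holoscat.grids import OpticalGrid
from holoscat.retrieval import RetrievedFieldSet, retrieve_fields
from holoscat.simulate import (PointSourceSet, make_masks, make_phase_screen,
                               simulate_measurements)

SOURCE_NA = 0.35
FOCUS = 30.0  # layer-to-focal-plane distance of the small scene (um)


@pytest.fixture(scope="session")
def grid64() -> OpticalGrid:
    return OpticalGrid(n_x=64, n_y=64, pitch=0.4, wavelength=0.55, na_max=0.65)


@pytest.fixture(scope="session")
def grid128() -> OpticalGrid:
    """The package's reference test grid (supports NA 0.35 collection)."""
    return OpticalGrid(n_x=128, n_y=128, pitch=0.4, wavelength=0.55,
                       na_max=0.4)


@pytest.fixture(scope="session")
def small_scene(grid64):
    """Three coplanar sources, screen, masks and noiseless measurements."""
    sources = PointSourceSet(x=[-6.0, 5.0, 1.0], y=[2.0, -4.0, 6.0],
                             z=[FOCUS] * 3, intensity=[1.0, 1.0, 1.0])
    screen = make_phase_screen(grid64, correlation_length=0.9, strength=2.5,
                               seed=11)
    masks = make_masks(grid64, count=36, macropixel=1, seed=21)
    measurements, truth = simulate_measurements(
        sources, screen, masks, photon_budget=None, seed=31,
        focus_distance=FOCUS, source_na=SOURCE_NA)
    return {"sources": sources, "screen": screen, "masks": masks,
            "measurements": measurements, "truth": truth, "grid": grid64}


@pytest.fixture(scope="session")
def truth_fields(small_scene) -> RetrievedFieldSet:
    """Ground-truth camera-plane fields of the small scene."""
    return RetrievedFieldSet(values=small_scene["truth"].fields_camera,
                             grid=small_scene["grid"], plane_z=0.0,
                             label="camera")


@pytest.fixture(scope="session")
def retrieved_small(small_scene):
    """Phase-retrieved fields of the small scene (noiseless, converged)."""
    fields, trace = retrieve_fields(small_scene["measurements"], n_states=3,
                                    max_iters=200, tol=1e-9, seed=41)
    return fields, trace


def random_field_values(grid: OpticalGrid, seed: int,
                        band_limited: bool = False) -> np.ndarray:
    """Circular complex Gaussian field, optionally band-limited."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
    if band_limited:
        from holoscat.propagation import fft2c, ifft2c

        vals = ifft2c(fft2c(vals) * grid.band_mask)
    return vals


def haar_unitary(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))
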