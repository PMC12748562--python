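"""Physical-optics simulator for incoherent sources behind a thin diffuser.

This module is the test bed for the whole pipeline: it builds incoherent
point-source objects (beads at one or two depths, or a spiral of foci), a
thin random phase screen standing in for the scattering layer, sets of
random phase masks for the modulator, and the camera measurements

    I_m = sum_n | F^-1[ E~_n K_m ] |^2 ,

the incoherent sum over sources of the intensity of each modulated field.

Geometry.  The coordinate origin (z = 0) is the plane the camera is
conjugate to (the microscope's focal plane); z increases toward the
detector.  The scattering layer sits ``focus_distance`` um downstream of
the focal plane (default 100 um), and each source ``n`` sits ``z_n`` um
behind the layer on the hidden side.  The optical train between layer and
camera (objective, relay, modulator at a Fourier plane) is collapsed into
exact Fourier-conjugate relations: the modulator plane is the Fourier plane
of the camera-conjugate plane, and absolute magnification is absorbed into
the grid.  The thin-layer model holds exactly by construction: the field of
source n at the layer is ``E_n = exp(i*phi_screen) * h_n`` with ``h_n`` the
free-space field of the point emitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import OpticalGrid
from .propagation import fft2c, ifft2c, point_source_field, propagate_values

__all__ = [
    "PointSourceSet",
    "PhaseScreen",
    "MaskSet",
    "SpeckleMeasurementSet",
    "SimulationTruth",
    "default_sim_grid",
    "make_phase_screen",
    "make_masks",
    "simulate_measurements",
    "make_spiral_fixture",
    "make_bead_fixture",
]

#: numerical aperture of the collection optics assumed by the simulator
DEFAULT_SOURCE_NA = 0.35


def default_sim_grid(n: int = 128) -> OpticalGrid:
    """Default simulation grid: n x n, 0.4 um pitch, lambda 0.55 um.

    ``na_max`` is set to 0.65 so that light scattered by a strongly
    diffusing screen (which broadens the 0.35-NA source band by the screen's
    divergence) still fits inside the sampled spatial-frequency band.
    """
    return OpticalGrid(n_x=n, n_y=n, pitch=0.4, wavelength=0.55, na_max=0.65)


@dataclass
class PointSourceSet:
    """Positions and relative intensities of independent incoherent emitters.

    ``z`` is the distance from the scattering layer in um, positive on the
    hidden side of the layer.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        self.intensity = np.atleast_1d(np.asarray(self.intensity, dtype=float))
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.intensity) == n) or n < 1:
            raise ValueError("x, y, z, intensity must share a common length >= 1")
        if np.any(self.intensity <= 0):
            raise ValueError("source intensities must be positive")

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_um": self.x, "y_um": self.y, "z_um": self.z,
             "intensity": self.intensity}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PointSourceSet":
        return cls(
            x=df["x_um"].to_numpy(),
            y=df["y_um"].to_numpy(),
            z=df["z_um"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointSourceSet":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class PhaseScreen:
    """Thin random phase screen: transmission exp(i * phase), |t| = 1."""

    phase: np.ndarray
    grid: OpticalGrid
    correlation_length: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != self.grid.shape:
            raise ValueError("phase shape does not match grid")

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(1j * self.phase)


@dataclass
class MaskSet:
    """M phase-only modulation masks at the Fourier (modulator) plane."""

    phases: np.ndarray  # (M, ny, nx), radians
    grid: OpticalGrid
    macropixel: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3 or self.phases.shape[1:] != self.grid.shape:
            raise ValueError("mask phases must be (M, ny, nx) on the grid")

    def __len__(self) -> int:
        return self.phases.shape[0]

    @property
    def values(self) -> np.ndarray:
        """Unit-modulus complex masks K_m."""
        return np.exp(1j * self.phases)


@dataclass
class SpeckleMeasurementSet:
    """Camera data: M modulated intensity images with their known masks."""

    images: np.ndarray  # (M, ny, nx), non-negative
    masks: MaskSet
    grid: OpticalGrid
    focus_distance: float = 100.0  # layer-to-focal-plane distance (um)
    source_distance: float = 100.0  # nominal source-to-layer distance (um)
    noise: dict | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1:] != self.grid.shape:
            raise ValueError("images must be (M, ny, nx) on the grid")
        if self.images.shape[0] != len(self.masks):
            raise ValueError("image count must equal mask count")
        if np.any(self.images < 0):
            raise ValueError("intensity images must be non-negative")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class SimulationTruth:
    """Ground truth returned by the simulator, for testing only."""

    sources: PointSourceSet
    screen: PhaseScreen
    layer_z: float  # axial coordinate of the layer (= focus_distance)
    fields_layer: np.ndarray  # (N, ny, nx): E_n = exp(i phi) h_n at the layer
    fields_camera: np.ndarray  # (N, ny, nx): fields at the camera-conjugate plane
    free_fields_layer: np.ndarray  # (N, ny, nx): h_n, no screen
    source_na: float = DEFAULT_SOURCE_NA


def make_phase_screen(
    grid: OpticalGrid,
    correlation_length: float = 0.9,
    strength: float = 2.5,
    seed: int | None = 0,
) -> PhaseScreen:
    """Gaussian random phase screen with a given lateral correlation length.

    White Gaussian noise is low-pass filtered (Gaussian kernel of sigma
    ``correlation_length``, periodic boundaries) and rescaled so the phase
    RMS equals ``strength`` radians.  ``strength = 0`` yields a transparent
    screen.  Deterministic for a given seed.
    """
    if correlation_length < grid.pitch:
        raise ValueError(
            f"correlation_length {correlation_length} um below pitch {grid.pitch} um"
        )
    if strength == 0.0:
        return PhaseScreen(phase=np.zeros(grid.shape), grid=grid,
                           correlation_length=correlation_length, seed=seed)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length / grid.pitch,
                                     mode="wrap")
    smooth -= smooth.mean()
    smooth *= strength / smooth.std()
    return PhaseScreen(phase=smooth, grid=grid,
                       correlation_length=correlation_length, seed=seed)


def make_masks(
    grid: OpticalGrid,
    count: int,
    macropixel: int = 1,
    seed: int | None = 0,
) -> MaskSet:
    """Random phase-only masks: i.i.d. uniform [0, 2pi) per macropixel."""
    if count < 1:
        raise ValueError("mask count must be >= 1")
    if macropixel < 1:
        raise ValueError("macropixel must be >= 1 pixel")
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    by = -(-ny // macropixel)
    bx = -(-nx // macropixel)
    blocks = rng.uniform(0.0, 2.0 * np.pi, size=(count, by, bx))
    phases = np.repeat(np.repeat(blocks, macropixel, axis=1), macropixel, axis=2)
    phases = phases[:, :ny, :nx]
    return MaskSet(phases=phases, grid=grid, macropixel=macropixel, seed=seed)


def simulate_measurements(
    sources: PointSourceSet,
    screen: PhaseScreen,
    masks: MaskSet,
    grid: OpticalGrid | None = None,
    photon_budget: float | None = None,
    seed: int | None = 0,
    focus_distance: float = 100.0,
    source_na: float = DEFAULT_SOURCE_NA,
) -> tuple[SpeckleMeasurementSet, SimulationTruth]:
    """Simulate the modulated incoherent measurements and return ground truth.

    For each source ``n`` the free-space field ``h_n`` at the layer is
    computed, multiplied by the screen transmission to give the layer field
    ``E_n``, propagated to the camera-conjugate plane, and Fourier
    transformed to the modulator plane (``E~_n``).  Each camera image then
    accumulates ``|F^-1[E~_n K_m]|^2`` incoherently over sources.  Optional
    shot noise draws each image from a Poisson law scaled so the mean total
    count per image equals ``photon_budget``.
    """
    if grid is None:
        grid = screen.grid
    if screen.grid.shape != grid.shape or masks.grid.shape != grid.shape:
        raise ValueError("sources, screen and masks must live on compatible grids")
    if len(masks) < 1:
        raise ValueError("mask set is empty")
    if np.any(sources.z < 0):
        raise ValueError("sources must lie on the hidden side of the layer (z >= 0)")

    n_src = len(sources)
    free_fields = np.empty((n_src,) + grid.shape, dtype=np.complex128)
    for n in range(n_src):
        h = point_source_field(
            grid, sources.x[n], sources.y[n], z_to_plane=sources.z[n],
            amplitude=np.sqrt(sources.intensity[n]), na=source_na,
        )
        free_fields[n] = h.values
    fields_layer = free_fields * screen.transmission[None, :, :]
    fields_camera = propagate_values(fields_layer, grid, -focus_distance)
    e_tilde = fft2c(fields_camera)

    images = np.empty((len(masks),) + grid.shape, dtype=float)
    kvals = masks.values
    for m in range(len(masks)):
        psi = ifft2c(e_tilde * kvals[m][None, :, :])
        images[m] = np.sum(np.abs(psi) ** 2, axis=0)

    noise_record = None
    if photon_budget is not None:
        rng = np.random.default_rng(seed)
        mean_total = float(images.sum(axis=(1, 2)).mean())
        scale = photon_budget / mean_total
        images = rng.poisson(images * scale).astype(float)
        noise_record = {"photon_budget": float(photon_budget), "seed": seed}

    measurements = SpeckleMeasurementSet(
        images=images, masks=masks, grid=grid,
        focus_distance=focus_distance,
        source_distance=float(np.mean(sources.z)),
        noise=noise_record,
    )
    truth = SimulationTruth(
        sources=sources, screen=screen, layer_z=focus_distance,
        fields_layer=fields_layer, fields_camera=fields_camera,
        free_fields_layer=free_fields, source_na=source_na,
    )
    return measurements, truth


def make_spiral_fixture(
    rho1: float = 10.0,
    rho2: float = 6.7,
    n_sources: int = 20,
    turns_total_angle: float = 4.0 * np.pi,
    dz: float = 0.5,
    z_base: float = 60.0,
) -> PointSourceSet:
    """Spiral of point sources in cylindrical coordinates.

    Source ``n`` (1-based) sits at radius ``rho1 - rho2*(n-1)/n_sources``,
    azimuth ``turns_total_angle*(n-1)/n_sources``, and axial position
    ``z_base + n*dz`` behind the layer, so the axial coverage is
    ``n_sources * dz``.  The defaults trace 20 foci over two full turns with
    a 10 um axial span.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    n = np.arange(1, n_sources + 1, dtype=float)
    rho = rho1 - rho2 * (n - 1) / n_sources
    if np.any(rho < 0):
        raise ValueError("spiral parameters give a negative radius")
    phi = turns_total_angle * (n - 1) / n_sources
    return PointSourceSet(
        x=rho * np.cos(phi),
        y=rho * np.sin(phi),
        z=z_base + n * dz,
        intensity=np.ones(n_sources),
    )


def make_bead_fixture(
    n_beads: int,
    plane_depths: list[float],
    min_separation: float = 5.0,
    seed: int | None = 0,
    lateral_extent: float = 30.0,
) -> PointSourceSet:
    """Random bead positions with a minimum pairwise lateral separation.

    Beads are drawn uniformly in a centred square of side ``lateral_extent``
    um and assigned round-robin to the given depths (um behind the layer).
    Raises if a placement satisfying ``min_separation`` cannot be found in
    1000 attempts.
    """
    if not plane_depths:
        raise ValueError("plane_depths must be non-empty")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    half = lateral_extent / 2.0
    xs: list[float] = []
    ys: list[float] = []
    for _ in range(n_beads):
        for attempt in range(1000):
            x = rng.uniform(-half, half)
            y = rng.uniform(-half, half)
            if all(np.hypot(x - xi, y - yi) >= min_separation
                   for xi, yi in zip(xs, ys)):
                xs.append(x)
                ys.append(y)
                break
        else:
            raise RuntimeError(
                f"could not place bead {len(xs) + 1} with min_separation "
                f"{min_separation} um in 1000 attempts"
            )
    depths = [plane_depths[i % len(plane_depths)] for i in range(n_beads)]
    return PointSourceSet(
        x=np.array(xs), y=np.array(ys), z=np.array(depths, dtype=float),
        intensity=np.ones(n_beads),
    )
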