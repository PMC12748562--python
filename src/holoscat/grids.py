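"""Sampling grids and complex wave fields.

Every array in the package lives on an :class:`OpticalGrid`: a uniformly
sampled lateral plane ``r = (x, y)`` with a fixed vacuum wavelength and a
declared maximum numerical aperture.  Coordinates are in micrometres with the
origin at the grid centre; ``z`` increases from the hidden object toward the
detector.  The spectral convention used throughout is the centred, unitary
discrete Fourier transform (zero frequency at the array centre).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

__all__ = ["OpticalGrid", "ComplexField"]


@dataclass(frozen=True)
class OpticalGrid:
    """Uniform sampling of a lateral optical plane.

    Parameters
    ----------
    n_x, n_y : int
        Pixel counts along x and y (``n_y`` rows, ``n_x`` columns).
    pitch : float
        Sampling interval in micrometres (same along both axes).
    wavelength : float
        Vacuum wavelength lambda in micrometres.
    na_max : float
        Largest numerical aperture the grid must support.  Spatial
        frequencies beyond ``na_max * k0`` are treated as outside the
        system's band and are removed by the propagation operators.
    """

    n_x: int
    n_y: int
    pitch: float
    wavelength: float
    na_max: float = 1.0

    def __post_init__(self) -> None:
        if self.n_x < 8 or self.n_y < 8:
            raise ValueError("grid must be at least 8x8 pixels")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")
        if not 0 < self.na_max <= 1.0:
            raise ValueError("na_max must lie in (0, 1]")
        # Nyquist: the band-limit NA must be sampled without aliasing.
        if self.pitch > self.wavelength / (2.0 * self.na_max):
            raise ValueError(
                f"pitch {self.pitch} um undersamples NA {self.na_max} at "
                f"wavelength {self.wavelength} um (Nyquist limit "
                f"{self.wavelength / (2 * self.na_max):.4g} um)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2*pi/lambda (rad/um)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def extent(self) -> tuple[float, float]:
        """Physical size (width_x, height_y) in um."""
        return (self.n_x * self.pitch, self.n_y * self.pitch)

    @cached_property
    def x(self) -> np.ndarray:
        """1D x-coordinates (um), origin at the centre pixel."""
        return (np.arange(self.n_x) - self.n_x // 2) * self.pitch

    @cached_property
    def y(self) -> np.ndarray:
        return (np.arange(self.n_y) - self.n_y // 2) * self.pitch

    @cached_property
    def xx(self) -> np.ndarray:
        return np.broadcast_to(self.x[None, :], self.shape)

    @cached_property
    def yy(self) -> np.ndarray:
        return np.broadcast_to(self.y[:, None], self.shape)

    @cached_property
    def kx(self) -> np.ndarray:
        """1D spatial frequencies along x (rad/um), centred."""
        return 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(self.n_x, d=self.pitch))

    @cached_property
    def ky(self) -> np.ndarray:
        return 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(self.n_y, d=self.pitch))

    @cached_property
    def k_sq(self) -> np.ndarray:
        """Centred map of kx^2 + ky^2 (rad^2/um^2)."""
        return self.kx[None, :] ** 2 + self.ky[:, None] ** 2

    @cached_property
    def band_mask(self) -> np.ndarray:
        """Boolean mask of frequencies within the na_max band."""
        return self.k_sq <= (self.na_max * self.k0) ** 2

    def aperture(self, na: float | None = None) -> np.ndarray:
        """Boolean pupil mask for a given NA (default ``na_max``)."""
        if na is None:
            return self.band_mask
        return self.k_sq <= (na * self.k0) ** 2

    def to_dict(self) -> dict:
        return {
            "n_x": self.n_x,
            "n_y": self.n_y,
            "pitch_um": self.pitch,
            "wavelength_um": self.wavelength,
            "na_max": self.na_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalGrid":
        return cls(
            n_x=int(d["n_x"]),
            n_y=int(d["n_y"]),
            pitch=float(d["pitch_um"]),
            wavelength=float(d["wavelength_um"]),
            na_max=float(d["na_max"]),
        )


@dataclass
class ComplexField:
    """A 2D complex wave field sampled on an :class:`OpticalGrid`.

    ``plane_z`` records the axial coordinate (um) of the plane the samples
    describe; ``label`` is free text such as ``"camera"`` or
    ``"correlation-plane"``.
    """

    values: np.ndarray
    grid: OpticalGrid
    plane_z: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def energy(self) -> float:
        """Total energy sum(|E|^2) in grid units."""
        return float(np.sum(np.abs(self.values) ** 2))

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def with_values(self, values: np.ndarray, *, plane_z: float | None = None,
                    label: str | None = None) -> "ComplexField":
        return ComplexField(
            values=values,
            grid=self.grid,
            plane_z=self.plane_z if plane_z is None else plane_z,
            label=self.label if label is None else label,
        )

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())
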