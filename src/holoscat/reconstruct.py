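"""Holographic 3D reconstruction through the virtual medium.

With the virtual layer ``S`` in hand, each field at the correlation plane
is conjugated, multiplied by ``S`` (undoing the common distortion),
Fourier transformed into the reconstruction frame and numerically
refocused over a z-range:

    I(r, z) = sum_n | P_z{ F[ E_n* S ] }(r) |^2 .

The stack lives in *reconstruction coordinates*: a demagnified, possibly
mirrored copy of object space whose mapping to physical micrometres is
recovered separately by the fixture-based coordinate calibration.  This
module also provides source detection on the stack, maximum-intensity
projections and interpolated FWHM measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import OpticalGrid
from .medium import VirtualMedium
from .propagation import fft2c, ifft2c, propagate_values
from .retrieval import RetrievedFieldSet
from .simulate import PointSourceSet

__all__ = [
    "ReconstructionStack",
    "reconstruct_volume",
    "detect_sources",
    "max_intensity_projection",
    "fwhm_measure",
    "fourier_upsample",
]


@dataclass
class ReconstructionStack:
    """Non-negative intensity volume I(x, y, z) with its z-axis."""

    values: np.ndarray  # (nz, ny, nx)
    z_values: np.ndarray  # um, reconstruction coordinates, monotonic
    grid: OpticalGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.z_values):
            raise ValueError("values must be (nz, ny, nx) matching z_values")
        if np.any(self.values < 0):
            raise ValueError("reconstructed intensity must be non-negative")
        dz = np.diff(self.z_values)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z-axis must be strictly monotonic")

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def slice_at(self, z: float) -> np.ndarray:
        """Nearest-plane slice at reconstruction coordinate z."""
        idx = int(np.argmin(np.abs(self.z_values - z)))
        return self.values[idx]


def reconstruct_volume(
    fields: RetrievedFieldSet,
    medium: VirtualMedium,
    z_samples: np.ndarray,
) -> ReconstructionStack:
    """Refocus the compensated fields over ``z_samples``.

    ``fields`` must live at the medium's plane.  The compensated fields
    are band-limited once before refocusing so the propagation is unitary
    across the whole stack (total energy constant in z).  The result is
    invariant under per-field global phases and any unitary mixture of the
    field set.
    """
    z_samples = np.atleast_1d(np.asarray(z_samples, dtype=float))
    if z_samples.size == 0:
        raise ValueError("z_samples must be non-empty")
    if fields.grid.shape != medium.grid.shape:
        raise ValueError("fields and medium live on different grids")
    grid = fields.grid
    g = fft2c(np.conj(fields.values) * medium.transmission[None])
    # band-limit once so every plane, including z=0, sees the same energy
    g = ifft2c(fft2c(g) * grid.band_mask[None])
    stack = np.empty((len(z_samples),) + grid.shape, dtype=float)
    for iz, z in enumerate(z_samples):
        prop = propagate_values(g, grid, float(z))
        stack[iz] = np.sum(np.abs(prop) ** 2, axis=0)
    order = np.argsort(z_samples)
    return ReconstructionStack(
        values=stack[order], z_values=z_samples[order], grid=grid,
        provenance={"n_fields": len(fields), "medium_plane_z": medium.plane_z,
                    "reference_index": medium.reference_index},
    )


def _quad_refine(vm: float, v0: float, vp: float) -> float:
    den = vm - 2.0 * v0 + vp
    if den >= 0:
        return 0.0
    return float(np.clip(0.5 * (vm - vp) / den, -0.5, 0.5))


def detect_sources(
    stack: ReconstructionStack,
    rel_threshold: float = 0.5,
    merge_radius: float | None = None,
) -> PointSourceSet | None:
    """3D local maxima above ``rel_threshold * max``, sub-pixel refined.

    Peaks are refined by 3-point quadratic fits along x, y and z, then
    merged laterally: a peak within ``merge_radius`` um (reconstruction
    coordinates; default two pixels) of a brighter accepted peak is
    dropped.  Returns ``None`` when nothing exceeds the threshold.
    """
    from scipy import ndimage

    vol = stack.values
    vmax = vol.max()
    if vmax <= 0:
        return None
    thr = rel_threshold * vmax
    local_max = (vol == ndimage.maximum_filter(vol, size=3, mode="nearest"))
    cand = np.argwhere(local_max & (vol >= thr))
    if cand.size == 0:
        return None
    if merge_radius is None:
        merge_radius = 2.0 * stack.grid.pitch

    nz, ny, nx = vol.shape
    pitch = stack.grid.pitch
    zax = stack.z_values
    peaks = []
    for iz, iy, ix in cand:
        v0 = vol[iz, iy, ix]
        dx = dy = dz = 0.0
        if 0 < ix < nx - 1:
            dx = _quad_refine(vol[iz, iy, ix - 1], v0, vol[iz, iy, ix + 1])
        if 0 < iy < ny - 1:
            dy = _quad_refine(vol[iz, iy - 1, ix], v0, vol[iz, iy + 1, ix])
        x = (ix + dx - nx // 2) * pitch
        y = (iy + dy - ny // 2) * pitch
        if 0 < iz < nz - 1:
            dz = _quad_refine(vol[iz - 1, iy, ix], v0, vol[iz + 1, iy, ix])
            step = 0.5 * (zax[iz + 1] - zax[iz - 1])
            z = zax[iz] + dz * step
        else:
            z = zax[iz]
        peaks.append((float(v0), x, y, float(z)))

    peaks.sort(reverse=True)
    kept: list[tuple[float, float, float, float]] = []
    for v, x, y, z in peaks:
        if all(np.hypot(x - kx, y - ky) >= merge_radius for _, kx, ky, _ in kept):
            kept.append((v, x, y, z))
    return PointSourceSet(
        x=np.array([p[1] for p in kept]),
        y=np.array([p[2] for p in kept]),
        z=np.array([p[3] for p in kept]),
        intensity=np.array([p[0] for p in kept]),
    )


def max_intensity_projection(stack: ReconstructionStack, axis: str = "z") -> np.ndarray:
    """Maximum-intensity projection along ``'x'``, ``'y'`` or ``'z'``."""
    ax = {"z": 0, "y": 1, "x": 2}.get(axis)
    if ax is None:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    return stack.values.max(axis=ax)


def fourier_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Sinc-interpolate a real image by zero-padding its centred spectrum."""
    if factor == 1:
        return np.asarray(image, dtype=float)
    ny, nx = image.shape
    spec = np.fft.fftshift(np.fft.fft2(image))
    py, px = ny * factor, nx * factor
    out = np.zeros((py, px), dtype=complex)
    y0 = py // 2 - ny // 2
    x0 = px // 2 - nx // 2
    out[y0:y0 + ny, x0:x0 + nx] = spec
    fine = np.fft.ifft2(np.fft.ifftshift(out)).real * factor * factor
    return fine


def fwhm_measure(
    stack: ReconstructionStack,
    position: tuple[float, float, float],
    axis: str = "x",
    window: float = 6.0,
    upsample: int = 8,
    lateral_scale: float = 1.0,
) -> float:
    """Interpolated full width at half maximum through a local maximum.

    ``position`` is (x, y, z) in reconstruction micrometres; the intensity
    profile along ``axis`` ('x' or 'y') is extracted from the nearest z
    plane with Fourier (sinc) interpolation, the half-maximum crossings are
    found by linear interpolation within ``+-window`` um, and the width is
    returned in calibrated micrometres (reconstruction width divided by
    ``lateral_scale``, the reconstruction magnification).  Invariant under
    intensity rescaling.  Returns NaN (with a warning) if the profile does
    not drop below half maximum inside the window.
    """
    import warnings

    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y' for lateral profiles")
    x0, y0, z0 = position
    plane = stack.slice_at(z0)
    fine = fourier_upsample(plane, upsample)
    pitch_f = stack.grid.pitch / upsample
    ny, nx = stack.grid.shape
    iy = (y0 / stack.grid.pitch + ny // 2) * upsample
    ix = (x0 / stack.grid.pitch + nx // 2) * upsample
    iy, ix = int(round(iy)), int(round(ix))
    half_w = int(round(window / pitch_f))
    if axis == "x":
        lo, hi = max(ix - half_w, 0), min(ix + half_w + 1, fine.shape[1])
        profile = fine[iy, lo:hi]
        centre = ix - lo
    else:
        lo, hi = max(iy - half_w, 0), min(iy + half_w + 1, fine.shape[0])
        profile = fine[lo:hi, ix]
        centre = iy - lo
    profile = np.maximum(profile, 0.0)
    # climb to the local peak in case the stated position is slightly off
    pk = centre
    while 0 < pk < len(profile) - 1:
        if profile[pk + 1] > profile[pk]:
            pk += 1
        elif profile[pk - 1] > profile[pk]:
            pk -= 1
        else:
            break
    vpk = profile[pk]
    if vpk <= 0:
        raise ValueError("no intensity at the stated position")
    half = vpk / 2.0

    def _cross(idx_range) -> float | None:
        prev = pk
        for i in idx_range:
            if profile[i] <= half:
                f = (profile[prev] - half) / (profile[prev] - profile[i])
                return prev + f * (i - prev)
            prev = i
        return None

    right = _cross(range(pk + 1, len(profile)))
    left = _cross(range(pk - 1, -1, -1))
    if right is None or left is None:
        warnings.warn("profile does not drop below half maximum inside the "
                      "window; FWHM undefined", stacklevel=2)
        return float("nan")
    width_rec = (right - left) * pitch_f
    return float(width_rec / lateral_scale)
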