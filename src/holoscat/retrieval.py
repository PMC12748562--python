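"""Mixed-state phase retrieval of mutually incoherent scattered fields.

A camera only records the summed intensity of mutually incoherent fields,
``I = sum_n |E_n|^2``.  With a set of known random phase masks ``K_m``
applied at the Fourier plane, each measurement is

    I_m = sum_n | F^-1[ E~_n K_m ] |^2 ,

and the fields can be recovered by alternating projections: for each mask,
form the modulated camera fields ``psi_n = F^-1[E~_n K_m]``, replace their
joint amplitude by the measurement,

    psi_n  <-  sqrt( I_m / sum_n |psi_n|^2 ) * psi_n ,

and map back, ``E~_n = F[psi_n] K_m*``.  One epoch sweeps all masks; the
iteration stops when the relative change of the intensity residual falls
below ``tol``.  The solution is defined only up to a per-field global phase
and an N x N unitary mixture of the fields — both measurement-equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import ComplexField, OpticalGrid
from .propagation import fft2c, ifft2c, propagate_values
from .simulate import SpeckleMeasurementSet

__all__ = [
    "RetrievedFieldSet",
    "ConvergenceTrace",
    "retrieve_fields",
    "measurement_residual",
]

_DENOM_GUARD = 1e-30


@dataclass
class RetrievedFieldSet:
    """N mutually incoherent complex fields on a shared grid and plane.

    The set is defined only up to per-field global phases and an N x N
    unitary mixture (see module docstring).
    """

    values: np.ndarray  # (N, ny, nx) complex
    grid: OpticalGrid
    plane_z: float = 0.0
    label: str = "camera"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError("values must be (N, ny, nx) on the grid")
        if self.values.shape[0] < 1:
            raise ValueError("at least one field required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fields contain non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    def field(self, n: int) -> ComplexField:
        return ComplexField(values=self.values[n], grid=self.grid,
                            plane_z=self.plane_z, label=f"{self.label}[{n}]")

    @property
    def energies(self) -> np.ndarray:
        return np.sum(np.abs(self.values) ** 2, axis=(1, 2))

    def propagate_to(self, z: float, label: str | None = None) -> "RetrievedFieldSet":
        """Propagate every field to the plane ``z`` (absolute coordinate)."""
        out = propagate_values(self.values, self.grid, z - self.plane_z)
        return RetrievedFieldSet(values=out, grid=self.grid, plane_z=z,
                                 label=label or self.label)

    def mixed_by(self, u: np.ndarray) -> "RetrievedFieldSet":
        """Apply a mixing matrix: field'_n = sum_m U[n, m] field_m."""
        u = np.asarray(u)
        out = np.tensordot(u, self.values, axes=(1, 0))
        return RetrievedFieldSet(values=out, grid=self.grid,
                                 plane_z=self.plane_z, label=self.label)


@dataclass
class ConvergenceTrace:
    """Per-epoch intensity residuals of the retrieval iteration."""

    residuals: list[float] = field(default_factory=list)
    n_epochs: int = 0
    stop_reason: str = ""

    @property
    def final_residual(self) -> float:
        return self.residuals[-1] if self.residuals else float("nan")


def _modeled_images(e_tilde: np.ndarray, kvals: np.ndarray) -> np.ndarray:
    out = np.empty((kvals.shape[0],) + e_tilde.shape[1:], dtype=float)
    for m in range(kvals.shape[0]):
        psi = ifft2c(e_tilde * kvals[m][None])
        out[m] = np.sum(np.abs(psi) ** 2, axis=0)
    return out


def measurement_residual(
    fields: RetrievedFieldSet, measurements: SpeckleMeasurementSet
) -> float:
    """Normalized L1 misfit between modeled and measured intensities.

    ``sum_m || sum_n |F^-1[E~_n K_m]|^2 - I_m ||_1 / sum_m || I_m ||_1``,
    computed with the fields taken at the camera plane.  Exactly invariant
    under any unitary mixing of the fields.
    """
    if fields.grid.shape != measurements.grid.shape:
        raise ValueError("fields and measurements live on different grids")
    e_tilde = fft2c(fields.values)
    model = _modeled_images(e_tilde, measurements.masks.values)
    total = float(np.abs(measurements.images).sum())
    return float(np.abs(model - measurements.images).sum() / total)


def retrieve_fields(
    measurements: SpeckleMeasurementSet,
    n_states: int,
    max_iters: int = 500,
    tol: float = 1e-6,
    seed: int | None = 0,
    order: str = "cyclic",
) -> tuple[RetrievedFieldSet, ConvergenceTrace]:
    """Recover ``n_states`` incoherent fields at the camera plane.

    Fields are initialized as i.i.d. circular complex Gaussians (seeded)
    and updated by cyclic alternating projections over the masks (one epoch
    = one pass).  ``order='random'`` reshuffles the mask order each epoch.
    Stops when the relative change of the residual over an epoch falls
    below ``tol`` or after ``max_iters`` epochs.

    Returns the camera-plane field set and the convergence trace.  Surplus
    states that decay below 1% of the total energy are flagged with a
    warning (the retrieval is then over-specified).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    n_masks = len(measurements)
    if n_states > n_masks:
        warnings.warn(
            f"n_states={n_states} exceeds mask count {n_masks}: problem is "
            "ill-posed", stacklevel=2,
        )
    total_intensity = measurements.images.sum()
    if total_intensity <= 0:
        raise ValueError("measurement stack is identically zero")
    if order not in ("cyclic", "random"):
        raise ValueError("order must be 'cyclic' or 'random'")

    grid = measurements.grid
    rng = np.random.default_rng(seed)
    shape = (n_states,) + grid.shape
    e_tilde = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    # scale so total modeled energy matches the mean measured energy
    mean_energy = float(measurements.images.sum(axis=(1, 2)).mean())
    e_tilde *= np.sqrt(mean_energy / np.sum(np.abs(e_tilde) ** 2))

    kvals = measurements.masks.values
    images = measurements.images
    norm = float(np.abs(images).sum())

    trace = ConvergenceTrace()
    prev_res = np.inf
    for epoch in range(max_iters):
        mask_order = np.arange(n_masks)
        if order == "random":
            rng.shuffle(mask_order)
        misfit = 0.0
        for m in mask_order:
            k = kvals[m][None]
            psi = ifft2c(e_tilde * k)
            denom = np.sum(np.abs(psi) ** 2, axis=0)
            misfit += float(np.abs(denom - images[m]).sum())
            factor = np.sqrt(
                np.divide(images[m], denom, out=np.ones_like(denom),
                          where=denom > _DENOM_GUARD)
            )
            np.putmask(factor, denom <= _DENOM_GUARD, 1.0)
            psi *= factor[None]
            e_tilde = fft2c(psi) * np.conj(k)
        res = misfit / norm
        trace.residuals.append(res)
        trace.n_epochs = epoch + 1
        if res < 1e-13 or abs(prev_res - res) < tol * max(res, 1e-300):
            trace.stop_reason = "converged"
            break
        prev_res = res
    else:
        trace.stop_reason = "max_iters"

    camera = ifft2c(e_tilde)
    fields = RetrievedFieldSet(values=camera, grid=grid, plane_z=0.0,
                               label="camera")
    energies = fields.energies
    weak = energies < 0.01 * energies.sum()
    if np.any(weak):
        warnings.warn(
            f"{int(weak.sum())} retrieved state(s) hold < 1% of total energy; "
            "n_states may be over-specified", stacklevel=2,
        )
    return fields, trace
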