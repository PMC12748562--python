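"""Field correlations, correlation-plane localization, and unitary demixing.

Scattered fields from neighbouring incoherent sources behind a thin
forward-scattering layer are correlated: at one internal plane (the
*correlation plane*, located at the layer) they differ only by a wavefront
tilt.  Three consequences are implemented here:

* the shift/tilt correlation ``C(dr, dk) = sum_r E_n(r - dr) E_m*(r)
  exp(i dk . r)`` between two fields, and the all-tilts-at-once map
  ``F[E_n* E_m]`` whose peak gives the optimal tilt for each pair;
* the correlation volume ``Gamma(r, z) = sum_{n,m} |F{P_z[E_n]* P_z[E_m]}|^2``
  whose off-centre maximum over z locates the plane of the layer;
* demixing: phase retrieval returns the fields only up to an N x N unitary
  mixture.  The demixing metric ``M(U) = sum_{n != m} max_{r != 0}
  |F[E'_n* E'_m](r)|`` is maximal when each transformed pair differs by a
  single tilt, i.e. when the mixture is undone.  ``M`` is maximized over
  the unitary group by Riemannian gradient ascent (tangent-space step,
  polar retraction, backtracking line search, seeded restarts).  For 3D
  objects, whose pairwise phase is quadratic rather than linear, demixing
  is run tile-by-tile where the quadratic phase is locally linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ComplexField, OpticalGrid
from .propagation import fft2c
from .retrieval import RetrievedFieldSet

__all__ = [
    "MixingMatrix",
    "TileLayout",
    "CorrelationVolume",
    "PlaneLocation",
    "TileDemixResult",
    "shift_tilt_correlation",
    "tilt_correlation_map",
    "pair_tilt_map",
    "correlation_volume",
    "locate_correlation_plane",
    "demix_unitary",
    "demix_tiled",
    "exclusion_mask",
]


# ---------------------------------------------------------------------------
# types

@dataclass
class MixingMatrix:
    """Unitary demixing matrix with optimization metadata."""

    matrix: np.ndarray
    metric_value: float
    metric_identity: float
    iterations: int
    converged: bool
    restart_metrics: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        u = np.asarray(self.matrix)
        err = np.linalg.norm(u @ u.conj().T - np.eye(u.shape[0]))
        if err > 1e-8:
            raise ValueError(f"matrix is not unitary (||UU+ - I|| = {err:.2e})")

    @property
    def unitarity_error(self) -> float:
        u = self.matrix
        return float(np.linalg.norm(u @ u.conj().T - np.eye(u.shape[0])))


@dataclass
class TileLayout:
    """Grid of partially overlapping tiles covering the field of view."""

    rows: int
    cols: int
    overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap fraction must lie in [0, 1)")

    @staticmethod
    def _edges(n: int, tiles: int, overlap: float) -> list[tuple[int, int]]:
        if tiles == 1:
            return [(0, n)]
        size = n / (tiles - (tiles - 1) * overlap)
        stride = size * (1.0 - overlap)
        out = []
        for i in range(tiles):
            a = int(round(i * stride))
            b = int(round(i * stride + size))
            out.append((a, min(b, n)))
        a, _ = out[-1]
        out[-1] = (a, n)
        return out

    def windows(self, shape: tuple[int, int]) -> list[dict]:
        """Per-tile pixel windows and cosine-taper weights for ``shape``.

        Every pixel of the field of view is covered by at least one tile.
        """
        ny, nx = shape
        rows = self._edges(ny, self.rows, self.overlap)
        cols = self._edges(nx, self.cols, self.overlap)
        tiles = []
        for r, (y0, y1) in enumerate(rows):
            for c, (x0, x1) in enumerate(cols):
                h, w = y1 - y0, x1 - x0
                wy = _taper(h, self.overlap, open_lo=(r == 0), open_hi=(r == self.rows - 1))
                wx = _taper(w, self.overlap, open_lo=(c == 0), open_hi=(c == self.cols - 1))
                tiles.append({
                    "row": r, "col": c,
                    "sly": slice(y0, y1), "slx": slice(x0, x1),
                    "weight": wy[:, None] * wx[None, :],
                })
        return tiles


def _taper(n: int, overlap: float, open_lo: bool, open_hi: bool) -> np.ndarray:
    """1D cosine-tapered window; edges at the field boundary stay flat."""
    w = np.ones(n)
    ramp = max(1, int(round(n * overlap)))
    t = 0.5 * (1.0 - np.cos(np.pi * (np.arange(ramp) + 0.5) / ramp))
    if not open_lo:
        w[:ramp] = t
    if not open_hi:
        w[-ramp:] = np.minimum(w[-ramp:], t[::-1])
    return w


@dataclass
class CorrelationVolume:
    """Tilt-correlation strength Gamma on (r, z)."""

    values: np.ndarray  # (nz, ny, nx), >= 0
    z_values: np.ndarray
    grid: OpticalGrid
    exclusion_radius: int = 3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.values.shape[0] != len(self.z_values):
            raise ValueError("one Gamma slice per z candidate required")
        if np.any(self.values < 0):
            raise ValueError("Gamma must be non-negative")


@dataclass
class PlaneLocation:
    """Result of the correlation-plane search."""

    z_hat: float
    confidence: float
    localized: bool
    profile: np.ndarray  # per-z masked maximum of Gamma


@dataclass
class TileDemixResult:
    """Per-tile demixing output for downstream stitched construction."""

    row: int
    col: int
    sly: slice
    slx: slice
    weight: np.ndarray
    mixing: MixingMatrix
    demixed: RetrievedFieldSet  # windowed, on the tile sub-grid


# ---------------------------------------------------------------------------
# correlations

def shift_tilt_correlation(
    e_n: ComplexField,
    e_m: ComplexField,
    shift: tuple[float, float] = (0.0, 0.0),
    tilt: tuple[float, float] = (0.0, 0.0),
) -> complex:
    """Discrete shift/tilt correlation of two fields.

    ``C = sum_r E_n(r - shift) E_m*(r) exp(i tilt . r)`` with ``shift`` in
    um (sub-pixel values realised by Fourier interpolation) and ``tilt`` in
    rad/um.  For ``n = m`` and zero shift/tilt this reduces to the total
    energy of the field.
    """
    if e_n.grid.shape != e_m.grid.shape:
        raise ValueError("fields live on different grids")
    grid = e_n.grid
    sx, sy = shift
    ex, ey = grid.extent
    if abs(sx) > ex or abs(sy) > ey:
        raise ValueError("shift exceeds the grid extent")
    vals = e_n.values
    if sx != 0.0 or sy != 0.0:
        ramp = np.exp(-1j * (grid.kx[None, :] * sx + grid.ky[:, None] * sy))
        vals = np.fft.ifft2(np.fft.fft2(vals) * np.fft.ifftshift(ramp))
    phase = np.exp(1j * (tilt[0] * grid.xx + tilt[1] * grid.yy))
    return complex(np.sum(vals * np.conj(e_m.values) * phase))


def pair_tilt_map(e_n: np.ndarray, e_m: np.ndarray) -> np.ndarray:
    """Correlation over all tilts at once: centred ``F[E_n* E_m]``.

    The peak magnitude is ``max |C|`` over tilts and the peak position, read
    on the grid's (kx, ky) axes, is the tilt that best aligns ``E_n`` with
    ``E_m`` (``E_n * exp(i k_peak . r) ~ E_m`` up to a constant).
    """
    return fft2c(np.conj(e_n) * e_m)


def tilt_correlation_map(fields: RetrievedFieldSet) -> np.ndarray:
    """All ordered-pair tilt maps, shape (N, N, ny, nx)."""
    n = len(fields)
    out = np.empty((n, n) + fields.grid.shape, dtype=np.complex128)
    for a in range(n):
        for b in range(n):
            out[a, b] = pair_tilt_map(fields.values[a], fields.values[b])
    return out


def exclusion_mask(shape: tuple[int, int], radius: int) -> np.ndarray:
    """Boolean mask that is False inside a centred disk of ``radius`` px."""
    ny, nx = shape
    yy = np.arange(ny) - ny // 2
    xx = np.arange(nx) - nx // 2
    rr = yy[:, None] ** 2 + xx[None, :] ** 2
    return rr > radius * radius


def _mirror(arr: np.ndarray) -> np.ndarray:
    """Map a centred map q -> -q (point reflection about zero frequency)."""
    return np.roll(arr[..., ::-1, ::-1], (1, 1), axis=(-2, -1))


def correlation_volume(
    fields: RetrievedFieldSet,
    z_candidates: np.ndarray,
    exclusion_radius: int = 3,
) -> CorrelationVolume:
    """Pairwise tilt-correlation strength at each candidate plane.

    For each z the fields are propagated there and
    ``Gamma(r, z) = sum_{n,m} |F[E_n* E_m](r)|^2`` accumulated over all
    ordered pairs, including n = m (whose contribution concentrates at
    r ~ 0 and is removed downstream by the exclusion disk).
    """
    if len(fields) < 2:
        raise ValueError("plane localization requires at least two fields")
    z_candidates = np.atleast_1d(np.asarray(z_candidates, dtype=float))
    if len(z_candidates) < 1:
        raise ValueError("at least one z candidate required")
    n = len(fields)
    gamma = np.empty((len(z_candidates),) + fields.grid.shape, dtype=float)
    for iz, z in enumerate(z_candidates):
        vals = fields.propagate_to(float(z)).values
        acc = np.zeros(fields.grid.shape, dtype=float)
        for a in range(n):
            for b in range(a, n):
                mag = np.abs(pair_tilt_map(vals[a], vals[b])) ** 2
                if a == b:
                    acc += mag
                else:
                    # the (b, a) map is the point mirror of the (a, b) map
                    acc += mag + _mirror(mag)
        gamma[iz] = acc
    return CorrelationVolume(values=gamma, z_values=z_candidates,
                             grid=fields.grid, exclusion_radius=exclusion_radius)


def locate_correlation_plane(volume: CorrelationVolume) -> PlaneLocation:
    """Arg-max of the off-centre correlation over z.

    The centred disk of the volume's exclusion radius is masked (removing
    the autocorrelation contribution at r ~ 0), the per-z maximum of the
    remainder is taken, and the z with the largest value wins.  Confidence
    is the ratio of the winning value to the median over z; below 1.05 the
    result is flagged as unlocalized.
    """
    if len(volume.z_values) < 2:
        raise ValueError("at least two z candidates required")
    mask = exclusion_mask(volume.values.shape[1:], volume.exclusion_radius)
    profile = np.max(volume.values * mask[None], axis=(1, 2))
    idx = int(np.argmax(profile))
    med = float(np.median(profile))
    confidence = float(profile[idx] / med) if med > 0 else np.inf
    return PlaneLocation(
        z_hat=float(volume.z_values[idx]),
        confidence=confidence,
        localized=bool(confidence >= 1.05),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# demixing

def _pair_peaks(
    u: np.ndarray, bmaps: np.ndarray, mask_flat: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Metric M(U), per-pair peak values and flat peak indices.

    ``bmaps`` holds the precomputed maps ``B_ab(r) = F[E_a* E_b](r)`` of the
    *unmixed* fields, flattened over r.  For any U the transformed pair
    maps follow without touching the pixel data:
    ``G_nm(r) = [conj(U) B(r) U^T]_nm``.
    """
    n = u.shape[0]
    u32 = u.astype(bmaps.dtype)
    t = np.tensordot(np.conj(u32), bmaps, axes=(1, 0))  # (n, b, P)
    # g[n, m, p] = sum_b u[m, b] t[n, b, p], done as batched BLAS matmuls
    g = np.matmul(t.transpose(0, 2, 1), u32.T).transpose(0, 2, 1)  # (n, m, P)
    mag = np.abs(g)
    mag[:, :, ~mask_flat] = -1.0
    flat_idx = np.argmax(mag, axis=2)
    peak = np.take_along_axis(mag, flat_idx[:, :, None], axis=2)[:, :, 0]
    metric = float(peak.sum() - np.trace(peak))
    return metric, peak, flat_idx


def _euclidean_gradient(
    u: np.ndarray, bmaps: np.ndarray, flat_idx: np.ndarray
) -> np.ndarray:
    """d M / d U* with each pair's arg-max pixel held fixed (subgradient)."""
    n = u.shape[0]
    grad = np.zeros_like(u)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            bnm = bmaps[:, :, flat_idx[a, b]].astype(np.complex128)
            g = np.conj(u[a]) @ bnm @ u[b]
            ag = abs(g)
            if ag < 1e-30:
                continue
            c = np.conj(g) / (2.0 * ag)
            grad[a] += c * (bnm @ u[b])
            grad[b] += np.conj(c) * (u[a] @ np.conj(bnm))
    return grad


def _polar_retract(x: np.ndarray) -> np.ndarray:
    w, _, vh = np.linalg.svd(x)
    return w @ vh


def _haar_unitary(n: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))


def demix_unitary(
    fields_at_plane: RetrievedFieldSet,
    seed: int | None = 0,
    max_iters: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 5,
    exclusion_radius: int = 3,
) -> tuple[MixingMatrix, RetrievedFieldSet]:
    """Maximize the pairwise tilt-correlation metric over the unitary group.

    Ascends ``M(U)`` from the identity and from ``n_restarts`` seeded Haar
    random unitaries by projected gradient steps in the tangent space of
    U(N) with polar retraction and backtracking step halving; the arg-max
    pixel of each pair is held fixed within each gradient step (subgradient
    of the max).  Returns the best unitary and the demixed field set
    ``E_n = sum_m U[n, m] E_m``.  By construction ``M(U_final) >=
    M(Identity)``.
    """
    n = len(fields_at_plane)
    grid_shape = fields_at_plane.grid.shape
    npix = grid_shape[0] * grid_shape[1]
    vals = fields_at_plane.values
    # precompute all base pair maps once; U only mixes them afterwards.
    # single precision suffices: peaks are located, not differentiated, and
    # every step is validated by the line search on the metric itself
    bmaps = np.empty((n, n, npix), dtype=np.complex64)
    for a in range(n):
        for b in range(n):
            bmaps[a, b] = pair_tilt_map(vals[a], vals[b]).ravel()
    mask_flat = exclusion_mask(grid_shape, exclusion_radius).ravel()

    rng = np.random.default_rng(seed)
    starts = [np.eye(n, dtype=np.complex128)]
    starts += [_haar_unitary(n, rng) for _ in range(n_restarts)]

    metric_id, _, _ = _pair_peaks(starts[0], bmaps, mask_flat)

    best_u = starts[0]
    best_metric = -np.inf
    best_iters = 0
    best_converged = False
    restart_metrics: list[float] = []

    for u0 in starts:
        u = u0.copy()
        metric, _, flat_idx = _pair_peaks(u, bmaps, mask_flat)
        step = 1.0
        stall = 0
        converged = False
        it = 0
        for it in range(1, max_iters + 1):
            egrad = _euclidean_gradient(u, bmaps, flat_idx)
            # project onto the tangent space of U(N) at u: xi = u * skew(u+ D)
            a_mat = u.conj().T @ egrad
            xi = u @ (a_mat - a_mat.conj().T) / 2.0
            xi_norm = np.linalg.norm(xi)
            if xi_norm < 1e-14:
                converged = True
                break
            tau = step / xi_norm
            improved = False
            for _ in range(12):
                cand = _polar_retract(u + tau * xi)
                m_new, _, idx_new = _pair_peaks(cand, bmaps, mask_flat)
                if m_new > metric:
                    improved = True
                    break
                tau *= 0.5
            if not improved:
                converged = True
                break
            rel = (m_new - metric) / max(metric, 1e-300)
            u, metric, flat_idx = cand, m_new, idx_new
            step = min(tau * xi_norm * 1.5, 10.0)
            if rel < tol:
                stall += 1
                if stall >= 3:
                    converged = True
                    break
            else:
                stall = 0
        restart_metrics.append(metric)
        if metric > best_metric:
            best_u, best_metric, best_iters = u, metric, it
            best_converged = converged

    mixing = MixingMatrix(
        matrix=best_u,
        metric_value=best_metric,
        metric_identity=metric_id,
        iterations=best_iters,
        converged=best_converged,
        restart_metrics=restart_metrics,
    )
    return mixing, fields_at_plane.mixed_by(best_u)


def demix_tiled(
    fields: RetrievedFieldSet,
    layout: TileLayout,
    seed: int | None = 0,
    **demix_kwargs,
) -> list[TileDemixResult]:
    """Run :func:`demix_unitary` independently on apodized tiles.

    Each tile is cut out with a cosine-tapered window (so tile edges fade
    smoothly) and demixed on its own sub-grid.  A 1 x 1 layout reproduces
    the global result exactly.  Results feed the stitched virtual-medium
    construction.
    """
    grid = fields.grid
    results: list[TileDemixResult] = []
    seeds = np.random.SeedSequence(seed).spawn(layout.rows * layout.cols)
    for i, tile in enumerate(layout.windows(grid.shape)):
        sly, slx = tile["sly"], tile["slx"]
        h = sly.stop - sly.start
        w = slx.stop - slx.start
        if h < 16 or w < 16:
            raise ValueError(f"tile ({tile['row']},{tile['col']}) is {h}x{w}; "
                             "tiles must be at least 16x16 pixels")
        subgrid = OpticalGrid(n_x=w, n_y=h, pitch=grid.pitch,
                              wavelength=grid.wavelength, na_max=grid.na_max)
        sub = fields.values[:, sly, slx] * tile["weight"][None]
        subset = RetrievedFieldSet(values=sub, grid=subgrid,
                                   plane_z=fields.plane_z,
                                   label=f"tile[{tile['row']},{tile['col']}]")
        tile_seed = int(seeds[i].generate_state(1)[0] % (2 ** 31))
        mixing, demixed = demix_unitary(subset, seed=tile_seed, **demix_kwargs)
        results.append(TileDemixResult(
            row=tile["row"], col=tile["col"], sly=sly, slx=slx,
            weight=tile["weight"], mixing=mixing, demixed=demixed,
        ))
    return results
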