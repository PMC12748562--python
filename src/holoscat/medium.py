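"""Construction of the virtual scattering medium.

At the correlation plane the field of source ``n`` factorises as
``E_n = S_o(r) h_n(r)``: a common random screen times the free-space field
of the emitter.  The relative phase of a pair is therefore

    arg( E_n* E_m ) = arg( h_n* h_m ) = Phi_nm(r) ,

a tilt for co-planar sources and a quadratic phase across depths.  After
estimating ``Phi_nm`` the fields are summed coherently and only the phase
kept:

    S(r) = exp( i * arg[ sum_n E_n exp(i Phi_nm) ] ) ,

a unit-modulus *virtual scattering layer* that carries the phase of
``S_o h_m`` (the screen as seen against reference field ``m``).  Because
phase estimation degrades when fields overlap weakly, construction is
incremental: it starts from the best-correlated pair and admits remaining
fields in order of their correlation against the running sum, skipping any
that fall below an admission threshold.  For 3D objects the construction
runs per demixed tile and the tiles are blended into one layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .correlation import TileLayout, TileDemixResult, exclusion_mask
from .grids import ComplexField, OpticalGrid
from .propagation import fft2c
from .retrieval import RetrievedFieldSet

__all__ = [
    "VirtualMedium",
    "InsufficientOverlapError",
    "estimate_relative_phase",
    "rank_pairs",
    "build_virtual_medium",
    "build_tiled_media",
    "stitch_virtual_medium",
]


class InsufficientOverlapError(ValueError):
    """Raised when two fields overlap too weakly for phase estimation."""


@dataclass
class VirtualMedium:
    """Unit-modulus phase screen S(r) at the located correlation plane."""

    phase: np.ndarray
    grid: OpticalGrid
    plane_z: float
    reference_index: int
    provenance: list[tuple[int, float]] = field(default_factory=list)
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != self.grid.shape:
            raise ValueError("phase shape does not match grid")

    @property
    def transmission(self) -> np.ndarray:
        """exp(i * phase); |S| = 1 everywhere by construction."""
        return np.exp(1j * self.phase)


# ---------------------------------------------------------------------------
# relative-phase estimation

def _overlap(a: np.ndarray, b: np.ndarray) -> float:
    num = float(np.sum(np.abs(a) * np.abs(b)))
    den = float(np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2)))
    return num / den if den > 0 else 0.0


def _fit_linear_phase(
    product: np.ndarray, grid: OpticalGrid, refine: int = 3
) -> tuple[float, float, float, float]:
    """Fit ``arg(product) ~ kx*x + ky*y + phi0`` (magnitude weighted).

    Coarse (kx, ky) from the sub-pixel peak of the centred FFT (parabolic
    interpolation around the arg-max bin), then refined by weighted
    circular-mean estimates of the residual phase gradient.  Returns
    (kx, ky, phi0, residual) with residual = 1 - |sum w| / sum |w| of the
    fully compensated product (0 for a perfect fit).
    """
    spec = np.abs(fft2c(product))
    iy, ix = np.unravel_index(int(np.argmax(spec)), spec.shape)

    def _parabolic(v_m, v_0, v_p):
        den = v_m - 2.0 * v_0 + v_p
        return 0.5 * (v_m - v_p) / den if den < 0 else 0.0

    ny, nx = spec.shape
    dy = _parabolic(spec[(iy - 1) % ny, ix], spec[iy, ix], spec[(iy + 1) % ny, ix])
    dx = _parabolic(spec[iy, (ix - 1) % nx], spec[iy, ix], spec[iy, (ix + 1) % nx])
    dkx = grid.kx[1] - grid.kx[0]
    dky = grid.ky[1] - grid.ky[0]
    kx = grid.kx[ix] + dx * dkx
    ky = grid.ky[iy] + dy * dky

    p = grid.pitch
    for _ in range(refine):
        w = product * np.exp(-1j * (kx * grid.xx + ky * grid.yy))
        gx = w[:, 1:] * np.conj(w[:, :-1])
        gy = w[1:, :] * np.conj(w[:-1, :])
        kx += float(np.angle(np.sum(gx))) / p
        ky += float(np.angle(np.sum(gy))) / p
    w = product * np.exp(-1j * (kx * grid.xx + ky * grid.yy))
    phi0 = float(np.angle(np.sum(w)))
    coherence = float(np.abs(np.sum(w * np.exp(-1j * phi0))) /
                      max(np.sum(np.abs(w)), 1e-300))
    return kx, ky, phi0, 1.0 - coherence


def _fit_quadratic_phase(
    product: np.ndarray, grid: OpticalGrid, smooth_sigma: float = 2.0
) -> tuple[np.ndarray, float]:
    """Weighted LS fit of a total-degree-2 phase polynomial, unwrap-free.

    The product field is smoothed (Gaussian, sigma in pixels), the phase
    *gradients* are estimated from adjacent-pixel phasors (gradients of a
    quadratic are linear, so no unwrapping is needed), and the five
    non-constant coefficients are solved by weighted least squares; the
    constant comes from the circular mean of the compensated product.
    """
    ps = (ndimage.gaussian_filter(product.real, smooth_sigma) +
          1j * ndimage.gaussian_filter(product.imag, smooth_sigma))
    p = grid.pitch
    xx, yy = grid.xx, grid.yy

    gx = ps[:, 1:] * np.conj(ps[:, :-1])  # phase step along x, weighted
    gy = ps[1:, :] * np.conj(ps[:-1, :])
    phx = np.angle(gx) / p  # d(phi)/dx at midpoints
    phy = np.angle(gy) / p
    wx = np.abs(gx).ravel()
    wy = np.abs(gy).ravel()

    xmx = ((xx[:, 1:] + xx[:, :-1]) / 2.0).ravel()
    ymx = np.broadcast_to(grid.y[:, None], gx.shape).ravel()
    xmy = np.broadcast_to(grid.x[None, :], gy.shape).ravel()
    ymy = ((yy[1:, :] + yy[:-1, :]) / 2.0).ravel()

    # Phi = a x^2 + b y^2 + c xy + d x + e y + f
    # dPhi/dx = 2a x + c y + d ; dPhi/dy = 2b y + c x + e
    zeros_x = np.zeros_like(xmx)
    zeros_y = np.zeros_like(xmy)
    ax = np.column_stack([2.0 * xmx, zeros_x, ymx, np.ones_like(xmx), zeros_x])
    ay = np.column_stack([zeros_y, 2.0 * ymy, xmy, zeros_y, np.ones_like(xmy)])
    design = np.vstack([ax * wx[:, None], ay * wy[:, None]])
    target = np.concatenate([phx.ravel() * wx, phy.ravel() * wy])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    a, b, c, d, e = coef

    phi_nc = a * xx ** 2 + b * yy ** 2 + c * xx * yy + d * xx + e * yy
    w = product * np.exp(-1j * phi_nc)
    f = float(np.angle(np.sum(w)))
    coherence = float(np.abs(np.sum(w * np.exp(-1j * f))) /
                      max(np.sum(np.abs(w)), 1e-300))
    return phi_nc + f, 1.0 - coherence


def estimate_relative_phase(
    e_n: ComplexField | np.ndarray,
    e_m: ComplexField | np.ndarray,
    grid: OpticalGrid | None = None,
    model: str = "linear",
    overlap_threshold: float = 1e-3,
    weight: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Estimate ``Phi_nm(r) = arg(E_n* E_m)`` as a linear or quadratic map.

    Returns ``(phi_map, residual)`` where ``phi_map`` satisfies
    ``E_n * exp(i phi_map) ~ E_m`` (up to a real amplitude ratio) and
    ``residual`` is the magnitude-weighted circular misfit in [0, 1].

    Raises :class:`InsufficientOverlapError` when the fields barely overlap
    (the regime where relative-phase estimation is unreliable).
    """
    if isinstance(e_n, ComplexField):
        grid = e_n.grid
        a, b = e_n.values, e_m.values
    else:
        a, b = np.asarray(e_n), np.asarray(e_m)
        if grid is None:
            raise ValueError("grid required when passing raw arrays")
    if a.shape != b.shape:
        raise ValueError("fields live on different grids")
    if _overlap(a, b) < overlap_threshold:
        raise InsufficientOverlapError(
            "insufficient overlap between fields for phase estimation")
    product = np.conj(a) * b
    if weight is not None:
        product = product * weight
    if model == "linear":
        kx, ky, phi0, residual = _fit_linear_phase(product, grid)
        return kx * grid.xx + ky * grid.yy + phi0, residual
    if model == "quadratic":
        return _fit_quadratic_phase(product, grid)
    raise ValueError("model must be 'linear' or 'quadratic'")


# ---------------------------------------------------------------------------
# ranking and incremental construction

def _pair_score(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    """Peak of the normalized tilt-correlation map of the ordered pair."""
    cmap = np.abs(fft2c(np.conj(a) * b))
    if mask is not None:
        cmap = cmap * mask
    norm = np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2))
    npix = a.size
    return float(cmap.max() * np.sqrt(npix) / norm) if norm > 0 else 0.0


def rank_pairs(
    fields: RetrievedFieldSet, exclusion_radius: int = 0
) -> list[tuple[int, int, float]]:
    """All ordered pairs ranked by normalized tilt-correlation peak.

    Scores are invariant to per-field global phases and equal 1 for a
    duplicated field.  With ``exclusion_radius > 0`` a centred disk of the
    correlation map is ignored (suppressing trivial self-overlap scores).
    """
    n = len(fields)
    if n < 2:
        raise ValueError("ranking requires at least two fields")
    mask = None
    if exclusion_radius > 0:
        mask = exclusion_mask(fields.grid.shape, exclusion_radius)
    scored = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            scored.append((i, j, _pair_score(fields.values[i],
                                             fields.values[j], mask)))
    scored.sort(key=lambda t: t[2], reverse=True)
    return scored


def build_virtual_medium(
    fields: RetrievedFieldSet,
    plane_z: float | None = None,
    model: str = "linear",
    admission_threshold: float = 0.1,
    fit_weight: np.ndarray | None = None,
    reference: int | None = None,
) -> VirtualMedium:
    """Coherently fuse fields into the virtual layer S(r), incrementally.

    Seeds the running sum with the top-ranked pair (the higher-energy
    member is the reference, fixing the overall phase), then repeatedly
    admits the remaining field with the highest normalized correlation
    against the current sum, estimating its relative phase against the sum
    and adding coherently.  Fields whose best correlation falls below
    ``admission_threshold`` are excluded and listed.  Returns
    ``S = exp(i arg[sum])`` with admission provenance.
    """
    n = len(fields)
    if n < 2:
        raise ValueError("virtual-medium construction requires >= 2 fields")
    z = fields.plane_z if plane_z is None else float(plane_z)
    grid = fields.grid
    vals = fields.values

    ranked = rank_pairs(fields)
    if reference is None:
        i, j, top_score = ranked[0]
        if top_score < admission_threshold:
            raise ValueError(
                "object fields mutually uncorrelated: top pair score "
                f"{top_score:.3g} below admission threshold {admission_threshold}")
        energies = fields.energies
        ref, other = (i, j) if energies[i] >= energies[j] else (j, i)
    else:
        # caller-imposed reference (e.g. to keep tiles mutually consistent):
        # seed with the best-correlated partner of that field
        ref = int(reference)
        i, j, top_score = next(p for p in ranked if ref in p[:2])
        if top_score < admission_threshold:
            raise ValueError(
                "object fields mutually uncorrelated: best score against the "
                f"reference is {top_score:.3g}, below {admission_threshold}")
        other = j if i == ref else i

    phi, _ = estimate_relative_phase(vals[other], vals[ref], grid, model=model,
                                     weight=fit_weight)
    total = vals[ref] + vals[other] * np.exp(1j * phi)
    provenance = [(ref, top_score), (other, top_score)]
    remaining = [k for k in range(n) if k not in (ref, other)]
    excluded: list[int] = []

    while remaining:
        scores = [(_pair_score(vals[k], total, None), k) for k in remaining]
        score, k = max(scores)
        if score < admission_threshold:
            excluded.extend(k for _, k in scores)
            break
        phi, _ = estimate_relative_phase(vals[k], total, grid, model=model,
                                         weight=fit_weight)
        total = total + vals[k] * np.exp(1j * phi)
        provenance.append((k, score))
        remaining.remove(k)

    return VirtualMedium(
        phase=np.angle(total), grid=grid, plane_z=z,
        reference_index=ref, provenance=provenance, excluded=sorted(excluded),
    )


def build_tiled_media(
    tile_results: list[TileDemixResult],
    model: str = "linear",
    admission_threshold: float = 0.1,
) -> list[VirtualMedium]:
    """Per-tile virtual layers with mutually consistent reference fields.

    Each tile's demixing matrix acts on the same underlying retrieved
    basis, so demixed fields are matched across tiles by comparing rows of
    the tile mixing matrices (Hungarian assignment on ``|U_t U_c*|``
    against the central tile).  The central tile picks its reference
    freely; every other tile is then built against the matched field, so
    that all tiles carry the phase of (approximately) the same reference
    source and can be stitched with low-order phase alignment.
    """
    from scipy.optimize import linear_sum_assignment

    if not tile_results:
        raise ValueError("no tiles given")
    rows = max(t.row for t in tile_results) + 1
    cols = max(t.col for t in tile_results) + 1
    centre = min(
        range(len(tile_results)),
        key=lambda i: (abs(tile_results[i].row - (rows - 1) / 2)
                       + abs(tile_results[i].col - (cols - 1) / 2)),
    )
    med_c = build_virtual_medium(tile_results[centre].demixed, model=model,
                                 admission_threshold=admission_threshold)
    u_c = tile_results[centre].mixing.matrix
    media: list[VirtualMedium] = []
    for i, tile in enumerate(tile_results):
        if i == centre:
            media.append(med_c)
            continue
        overlap = np.abs(tile.mixing.matrix @ u_c.conj().T)
        ti, ci = linear_sum_assignment(-overlap)
        match = {c: t for t, c in zip(ti, ci)}
        ref = int(match[med_c.reference_index])
        media.append(build_virtual_medium(
            tile.demixed, model=model, admission_threshold=admission_threshold,
            reference=ref))
    return media


# ---------------------------------------------------------------------------
# stitching tiled constructions

def stitch_virtual_medium(
    per_tile_media: list[VirtualMedium],
    layout: TileLayout,
    grid: OpticalGrid,
    align: str = "linear",
) -> VirtualMedium:
    """Blend per-tile virtual layers into one full-field layer.

    Tile phases are defined only up to their own reference field, so before
    blending each tile is phase-aligned to the already-stitched mosaic on
    their overlap: ``align='constant'`` removes the best-fit constant
    offset, ``align='linear'`` (default) removes a best-fit tilt plus
    offset, which also absorbs reference-field differences between tiles of
    co-planar sources.  Blending uses the cosine-taper tile weights; the
    output has |S| = 1 everywhere.
    """
    tiles = layout.windows(grid.shape)
    if len(per_tile_media) != len(tiles):
        raise ValueError(
            f"expected {len(tiles)} tiles for layout, got {len(per_tile_media)}")
    if align not in ("constant", "linear"):
        raise ValueError("align must be 'constant' or 'linear'")
    if len(tiles) == 1:
        med = per_tile_media[0]
        return VirtualMedium(phase=med.phase.copy(), grid=grid,
                             plane_z=med.plane_z,
                             reference_index=med.reference_index,
                             provenance=list(med.provenance),
                             excluded=list(med.excluded))

    mosaic = np.zeros(grid.shape, dtype=np.complex128)
    weight = np.zeros(grid.shape, dtype=float)

    # start from the central tile and grow outward so every new tile
    # overlaps the existing mosaic
    order = sorted(
        range(len(tiles)),
        key=lambda t: (abs(tiles[t]["row"] - (layout.rows - 1) / 2)
                       + abs(tiles[t]["col"] - (layout.cols - 1) / 2)),
    )
    plane_z = per_tile_media[order[0]].plane_z
    for t in order:
        tile, med = tiles[t], per_tile_media[t]
        if med.phase.shape != tile["weight"].shape:
            raise ValueError(f"tile {t} phase does not conform to the layout")
        sly, slx = tile["sly"], tile["slx"]
        tvals = np.exp(1j * med.phase) * tile["weight"]
        m_patch = mosaic[sly, slx]
        ov = (np.abs(m_patch) > 0) & (tile["weight"] > 0)
        if np.any(ov):
            prod = np.where(ov, np.conj(tvals) * m_patch, 0.0)
            if align == "constant":
                offset = np.angle(np.sum(prod))
                tvals = tvals * np.exp(1j * offset)
            else:
                sub = OpticalGrid(
                    n_x=prod.shape[1], n_y=prod.shape[0], pitch=grid.pitch,
                    wavelength=grid.wavelength, na_max=grid.na_max)
                kx, ky, phi0, _ = _fit_linear_phase(prod, sub, refine=3)
                tvals = tvals * np.exp(1j * (kx * sub.xx + ky * sub.yy + phi0))
        mosaic[sly, slx] += tvals
        weight[sly, slx] += tile["weight"]

    if np.any(weight <= 0):
        raise ValueError("tile layout leaves uncovered pixels")
    provenance = [p for med in per_tile_media for p in med.provenance]
    return VirtualMedium(
        phase=np.angle(mosaic), grid=grid, plane_z=plane_z,
        reference_index=per_tile_media[order[0]].reference_index,
        provenance=provenance,
        excluded=sorted({e for med in per_tile_media for e in med.excluded}),
    )
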