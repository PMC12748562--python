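"""Evaluation against ground truth: coordinate calibration and image metrics.

The reconstruction lives in a synthetic coordinate frame (the Fourier
conjugate of the virtual layer), related to object space by a lateral
similarity (magnification + rotation + possible mirror) and an affine
z-map.  Those parameters carry no information about the object itself, so
they are recovered empirically by least squares on matched
detection/ground-truth pairs.  PSNR and SSIM between reconstruction and
ground truth are computed after rigid registration, mirroring how
reconstructions are compared with a separately acquired reference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.metrics import structural_similarity
from skimage.registration import phase_cross_correlation

from .grids import OpticalGrid
from .propagation import point_source_field
from .reconstruct import ReconstructionStack, fourier_upsample
from .simulate import PointSourceSet

__all__ = [
    "CoordinateCalibration",
    "calibrate_coordinates",
    "image_metrics",
    "ground_truth_image",
    "resample_to_object_frame",
    "best_focus_depth",
]

PSNR_CAP_DB = 100.0


@dataclass
class CoordinateCalibration:
    """Similarity map from reconstruction coordinates to object space.

    ``object_xy = rotation @ rec_xy / magnification + translation`` and
    ``object_z = z_scale * rec_z + z_offset``.  ``magnification`` is the
    lateral scale of the reconstruction relative to the object (rec um per
    object um); ``parity`` is -1 when the reconstruction is mirrored.
    """

    magnification: float
    rotation: np.ndarray  # 2x2 orthogonal, det = parity
    translation: np.ndarray  # (2,), object-frame um
    parity: int
    z_scale: float
    z_offset: float
    residual_rms: float
    n_matched: int
    z_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.magnification == 0 or self.z_scale == 0:
            raise ValueError("magnification and z-scale must be nonzero")

    def to_object(self, x, y, z=None):
        """Map reconstruction coordinates into object space (um)."""
        xy = np.vstack([np.atleast_1d(x), np.atleast_1d(y)])
        obj = (self.rotation @ xy) / self.magnification + self.translation[:, None]
        if z is None:
            return obj[0], obj[1]
        zobj = self.z_scale * np.atleast_1d(z) + self.z_offset
        return obj[0], obj[1], zobj

    def to_rec(self, x, y, z=None):
        """Inverse map: object space into reconstruction coordinates."""
        xy = np.vstack([np.atleast_1d(x), np.atleast_1d(y)])
        rec = self.rotation.T @ ((xy - self.translation[:, None]) *
                                 self.magnification)
        if z is None:
            return rec[0], rec[1]
        zrec = (np.atleast_1d(z) - self.z_offset) / self.z_scale
        return rec[0], rec[1], zrec


def _similarity_fit(rec: np.ndarray, obj: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Least-squares ``obj ~ s R rec + t`` with R proper-orthogonal.

    Standard scaled-Procrustes (Kabsch/Umeyama) solution for matched 2D
    point sets given as (2, n) arrays.  Returns (s, R, t, rms).
    """
    mu_r = rec.mean(axis=1, keepdims=True)
    mu_o = obj.mean(axis=1, keepdims=True)
    rc = rec - mu_r
    oc = obj - mu_o
    cov = oc @ rc.T
    u, sv, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    rot = u @ corr @ vt
    var_r = np.sum(rc ** 2)
    s = float(np.sum(np.diag(corr) * sv) / var_r) if var_r > 0 else 1.0
    t = mu_o - s * rot @ mu_r
    resid = obj - (s * rot @ rec + t)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=0))))
    return s, rot, t[:, 0], rms


def calibrate_coordinates(
    detections: PointSourceSet, truth: PointSourceSet
) -> CoordinateCalibration:
    """Fit the reconstruction-to-object coordinate map on matched pairs.

    Both mirror parities and a sweep of trial rotations are explored; for
    each, detections are matched one-to-one to ground-truth sources by
    minimum total distance (Hungarian assignment) and the similarity is
    refined by scaled Procrustes, iterating match and fit.  The z map is an
    independent affine fit on the matched pairs (``z_scale = 1`` and mean
    offset when the detections span a single depth).  Requires at least 3
    matched pairs.
    """
    nd, nt = len(detections), len(truth)
    if min(nd, nt) < 3:
        raise ValueError("calibration requires at least 3 matched pairs")
    rec = np.vstack([detections.x, detections.y])
    obj = np.vstack([truth.x, truth.y])
    rec_c = rec - rec.mean(axis=1, keepdims=True)
    obj_c = obj - obj.mean(axis=1, keepdims=True)
    scale0 = (np.sqrt(np.mean(np.sum(obj_c ** 2, axis=0))) /
              max(np.sqrt(np.mean(np.sum(rec_c ** 2, axis=0))), 1e-12))

    best = None
    for parity in (1, -1):
        flip = np.diag([float(parity), 1.0])
        for theta in np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False):
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]]) @ flip
            cand = scale0 * rot @ rec_c + obj.mean(axis=1, keepdims=True)
            pair_r = pair_o = None
            for _ in range(4):
                dists = np.linalg.norm(cand[:, :, None] - obj[:, None, :], axis=0)
                ri, oi = optimize.linear_sum_assignment(dists)
                pair_r, pair_o = rec[:, ri], obj[:, oi]
                sc, rt, tr, rms = _similarity_fit(flip @ pair_r, pair_o)
                cand = sc * rt @ flip @ rec + tr[:, None]
            key = (rms, -len(ri))
            if best is None or key < best[0]:
                best = (key, parity, sc, rt @ flip, tr, rms,
                        detections.z[ri], truth.z[oi], len(ri))
    _, parity, sc, rot, tr, rms, z_rec, z_obj, n_matched = best

    z_degenerate = bool(np.ptp(z_rec) < 1e-9 or np.ptp(z_obj) < 1e-9)
    if z_degenerate:
        z_scale, z_offset = 1.0, float(np.mean(z_obj - z_rec))
    else:
        a = np.vstack([z_rec, np.ones_like(z_rec)]).T
        (z_scale, z_offset), *_ = np.linalg.lstsq(a, z_obj, rcond=None)
    return CoordinateCalibration(
        magnification=1.0 / sc,
        rotation=rot,
        translation=tr,
        parity=parity,
        z_scale=float(z_scale),
        z_offset=float(z_offset),
        residual_rms=rms,
        n_matched=int(n_matched),
        z_degenerate=z_degenerate,
    )


def _fourier_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    spec = np.fft.fft2(image)
    ny, nx = image.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    spec = spec * np.exp(-2j * np.pi * (fy * shift[0] + fx * shift[1]))
    return np.fft.ifft2(spec).real


def image_metrics(image: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """(PSNR in dB, SSIM) between two non-negative intensity images.

    Both images are background-subtracted (1st percentile), normalized to
    unit peak, and rigidly registered by the sub-pixel cross-correlation
    peak (applied as a periodic Fourier shift, so the metric is exactly
    symmetric in its arguments).  PSNR = 10 log10(1 / MSE), capped at
    100 dB; SSIM uses the standard constants (k1 = 0.01, k2 = 0.03, unit
    dynamic range, 11-pixel Gaussian window of sigma 1.5).
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference sizes differ")
    if np.any(image < 0) or np.any(reference < 0):
        raise ValueError("intensity images must be non-negative")

    def _norm(a: np.ndarray) -> np.ndarray:
        a = a - np.percentile(a, 1.0)
        a = np.clip(a, 0.0, None)
        peak = a.max()
        return a / peak if peak > 0 else a

    a = _norm(image)
    b = _norm(reference)
    # antisymmetrized shift estimate: exactly reversed when arguments swap
    s_ab, *_ = phase_cross_correlation(b, a, upsample_factor=50,
                                       normalization=None)
    s_ba, *_ = phase_cross_correlation(a, b, upsample_factor=50,
                                       normalization=None)
    shift = (np.asarray(s_ab) - np.asarray(s_ba)) / 2.0
    a = np.clip(_fourier_shift(a, tuple(shift)), 0.0, None)

    mse = float(np.mean((a - b) ** 2))
    psnr = PSNR_CAP_DB if mse <= 10 ** (-PSNR_CAP_DB / 10.0) else float(
        10.0 * np.log10(1.0 / mse))
    ssim = float(structural_similarity(
        b, a, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, win_size=11,
    ))
    return psnr, ssim


def ground_truth_image(
    sources: PointSourceSet,
    grid: OpticalGrid,
    focal_depth: float,
    na: float = 0.35,
) -> np.ndarray:
    """Ideal scattering-free widefield image focused ``focal_depth`` um
    behind the layer.

    Each source contributes the diffraction-limited incoherent PSF at
    numerical aperture ``na``, defocused by its distance from the focal
    plane — the image a reference camera without the scattering layer
    would record.
    """
    img = np.zeros(grid.shape)
    for n in range(len(sources)):
        f = point_source_field(
            grid, sources.x[n], sources.y[n],
            z_to_plane=abs(float(sources.z[n]) - focal_depth),
            amplitude=np.sqrt(sources.intensity[n]), na=na,
        )
        img += np.abs(f.values) ** 2
    return img


def resample_to_object_frame(
    rec_image: np.ndarray,
    grid: OpticalGrid,
    calibration: CoordinateCalibration,
    upsample: int = 4,
) -> np.ndarray:
    """Map a reconstruction-frame image onto the object-frame grid.

    The reconstruction slice is sinc-upsampled (it is nearly
    band-limited), then sampled at the reconstruction positions of each
    object-frame pixel through the calibration's inverse map.  Output is on
    the same grid interpreted as object-space micrometres.
    """
    fine = np.clip(fourier_upsample(rec_image, upsample), 0.0, None)
    pitch_f = grid.pitch / upsample
    ny, nx = grid.shape
    xo = np.broadcast_to(grid.x[None, :], grid.shape).ravel()
    yo = np.broadcast_to(grid.y[:, None], grid.shape).ravel()
    xr, yr = calibration.to_rec(xo, yo)
    col = xr / pitch_f + (nx // 2) * upsample
    row = yr / pitch_f + (ny // 2) * upsample
    out = ndimage.map_coordinates(fine, [row, col], order=1, mode="constant",
                                  cval=0.0)
    return out.reshape(grid.shape)


def best_focus_depth(
    stack: ReconstructionStack,
    lateral_positions: tuple[np.ndarray, np.ndarray],
    halfwidth: int = 1,
) -> float:
    """Reconstruction z of best focus for a group of lateral positions.

    Sums the stack intensity in small windows around the given (x, y)
    reconstruction positions at every plane and returns the sub-plane
    quadratic-refined arg-max.
    """
    xs, ys = lateral_positions
    ny, nx = stack.grid.shape
    pitch = stack.grid.pitch
    profile = np.zeros(len(stack.z_values))
    for x, y in zip(np.atleast_1d(xs), np.atleast_1d(ys)):
        ix = int(round(x / pitch + nx // 2))
        iy = int(round(y / pitch + ny // 2))
        sly = slice(max(iy - halfwidth, 0), min(iy + halfwidth + 1, ny))
        slx = slice(max(ix - halfwidth, 0), min(ix + halfwidth + 1, nx))
        profile += stack.values[:, sly, slx].sum(axis=(1, 2))
    i = int(np.argmax(profile))
    z = stack.z_values
    if 0 < i < len(z) - 1:
        num = profile[i - 1] - profile[i + 1]
        den = profile[i - 1] - 2 * profile[i] + profile[i + 1]
        if den < 0:
            frac = float(np.clip(0.5 * num / den, -0.5, 0.5))
            return float(z[i] + frac * 0.5 * (z[i + 1] - z[i - 1]))
    return float(z[i])
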