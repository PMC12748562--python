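# holoscat

Holographic 3D imaging of spatially incoherent objects hidden behind a
scattering layer, via a numerically constructed **virtual scattering
medium**.

## The problem

Fluorescent sources emit spatially incoherent light: a camera behind a
scattering layer records only a low-contrast sum of speckle intensities,
`I = Σ_n |E_n|²`, with no phase and no interference between sources.
Classical speckle-correlation imaging fails in the microscopy regime,
where the object sits only tens of micrometres behind the scatterer.
`holoscat` implements a field-based alternative for this regime and a
full physical-optics simulator to validate it, so the entire method runs
and is tested without experimental data. The intended users are
computational-optics and microscopy researchers who want a working,
inspectable reference implementation of each stage.

## The method

1. **Mixed-state phase retrieval.** The scattered light is modulated by
   M known random phase masks `K_m` at a Fourier plane, giving
   `I_m = Σ_n |F⁻¹[Ẽ_n K_m]|²`. Alternating projections (amplitude
   replacement per mask) recover N mutually incoherent fields — up to an
   unavoidable N×N unitary mixture.
2. **Correlation plane.** For a thin forward scatterer, fields of
   neighbouring sources differ at the layer by a pure wavefront tilt
   (memory effect). The plane maximizing
   `Γ(r, z) = Σ_{n,m} |F[P_z E_n* · P_z E_m](r)|²` over z (excluding
   r ≈ 0) locates the layer; an autofocus sweep refines it.
3. **Demixing.** The metric
   `M(U) = Σ_{n≠m} max_{r≠0} |F[E'_n* E'_m](r)|` is maximized over the
   unitary group (Riemannian gradient ascent with polar retraction and
   seeded restarts); it peaks when each pair differs by a single tilt,
   i.e. when the mixture is undone. For 3D objects demixing runs on a
   3×3 grid of overlapping tiles, where the pairwise quadratic phase is
   locally linear.
4. **Virtual medium.** Per-source fields are phase-aligned
   (`Φ_nm = arg(E_n* E_m)`, linear or quadratic model) and summed
   coherently, starting from the best-correlated pair and admitting
   fields by correlation: `S(r) = exp(i·arg Σ_n E_n e^{iΦ_nm})`, a
   unit-modulus phase screen mimicking the real layer's distortion.
5. **Reconstruction.** `I(r, z) = Σ_n |P_z{F[E_n* S]}(r)|²` refocuses
   every source into a diffraction-limited 3D image; detected peaks are
   mapped to object micrometres by a fixture-based similarity + affine-z
   calibration, and scored with PSNR/SSIM against the scattering-free
   ground-truth image.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Five bead-like emitters on one plane 100 µm behind a strongly
scattering screen, 120 modulation masks, noiseless:

```python
import numpy as np
from holoscat import (OpticalGrid, PointSourceSet, make_phase_screen,
                      make_masks, simulate_measurements,
                      HolographicImagingModel, calibrate_coordinates)

grid = OpticalGrid(n_x=192, n_y=192, pitch=0.4, wavelength=0.55, na_max=0.65)
beads = PointSourceSet(x=[-8.0, 5.0, 2.0, -3.0, 9.0],
                       y=[3.0, -6.0, 8.0, -9.0, 1.0],
                       z=[100.0] * 5, intensity=[1.0] * 5)
screen = make_phase_screen(grid, correlation_length=0.9, strength=2.5, seed=7)
masks = make_masks(grid, count=120, seed=8)
measurements, truth = simulate_measurements(beads, screen, masks,
                                            focus_distance=100.0)

model = HolographicImagingModel(measurements, n_states=5,
                                z_candidates=np.arange(61.0, 141.1, 2.0))
result = model.fit(seed=0)
print(result.summary())

stack = result.reconstruct(np.arange(-6.0, 6.01, 0.25))
detections = result.detect(rel_threshold=0.4, merge_radius=0.8)
cal = calibrate_coordinates(detections, beads)
x, y, z = cal.to_object(detections.x, detections.y, detections.z)
```

This prints:

```
Holographic imaging through a virtual scattering medium
========================================================
measurements               120 masked images (192x192)
incoherent states            5
retrieval epochs             7  (residual 1.345e-15, converged)
correlation plane z        99.90 um  (arg-max 99.40, confidence 41.60)
demixing                global
  metric M(U)/M(I)         2.136  (unitarity err 1.8e-15)
virtual medium          reference field 0, 5 admitted, 0 excluded
phase model             linear

detected sources (object frame, um):
  x= -8.02  y= +3.01
  x= -3.03  y= -9.02
  x= +2.12  y= +7.94
  x= +5.05  y= -6.07
  x= +8.87  y= +1.14
lateral position error (rms): 0.114 um
```

Reading it: retrieval converged to machine precision (noiseless data);
the layer was found at 99.9 µm from the focal plane (truth: 100 µm) with
high confidence; demixing doubled the pairwise tilt-correlation metric
relative to the raw mixture; all five fields entered the virtual layer;
and after calibration all five beads are localized to ~0.1 µm — an order
of magnitude below the 0.96 µm Rayleigh limit of the NA-0.35 system.

The same pipeline is scriptable from the shell:

```
holoscat run --config my_run.yaml --out runs/demo --seed 1
```

with per-stage commands (`simulate`, `retrieve`, `locate-plane`,
`demix`, `build-medium`, `reconstruct`, `evaluate`) operating on the
bundle directories each stage writes.

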