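# Methods

`holoscat` reconstructs three-dimensional arrangements of spatially
incoherent point emitters (e.g. fluorescent beads) hidden behind a thin,
strongly scattering layer, from intensity-only camera data. This note
describes the physical model, the estimation procedure, the synthetic
data used to validate it, and the numerical choices behind both.

## Physical model

Each independent emitter `n` radiates light that is mutually incoherent
with every other emitter. Its field at the scattering layer factorises,
for a thin layer, as

    E_n(r) = S_o(r) h_n(r),

where `h_n` is the free-space field of a point source at the emitter's
3D position and `S_o` is a unit-modulus random phase screen common to
all sources. The camera cannot measure fields of incoherent light
directly; it records, for each of M known phase-only modulation patterns
`K_m` applied at a Fourier plane,

    I_m = sum_n | F^-1[ E~_n K_m ] |^2 ,

the incoherent sum of the modulated per-source intensities (`E~_n` is
the field at the modulator plane, `F` the unitary Fourier transform).

Scalar diffraction is handled throughout by band-limited
angular-spectrum propagation `P_z` (exact one-step propagation in the
spatial-frequency domain, evanescent components removed, spectrum
clamped to the grid's declared maximum NA). Coordinates: `x, y, z` in
micrometres, origin at the camera-conjugate (focal) plane, `z`
increasing from the hidden object toward the detector.

## Estimation chain

1. **Mixed-state phase retrieval** (`retrieval`). With `N` states
   initialized as circular complex Gaussians, alternating projections
   sweep the masks cyclically: modulate, replace the joint amplitude by
   the measurement, demodulate. Noiseless simulated data converges to
   intensity residuals near machine precision within ~10–30 epochs. The
   solution is determined only up to per-field global phases and an
   N×N unitary mixture — both leave every `I_m` unchanged.

2. **Correlation-plane search** (`correlation`). Fields from nearby
   sources differ, at the plane of the scattering layer, by a pure
   wavefront tilt (the field-correlation form of the memory effect). The
   functional

        Gamma(r, z) = sum_{n,m} | F[ P_z[E_n]* P_z[E_m] ](r) |^2

   is evaluated on a coarse z grid (default 2 µm step), a centred disk
   of 3 px is masked to remove the n = m autocorrelation, and the
   arg-max over z of the masked maximum locates the layer; a second pass
   refines on a 0.4 µm grid. A confidence ratio (peak over median) below
   1.05 flags an unlocalized result.

3. **Unitary demixing** (`correlation`). The metric

        M(U) = sum_{n != m} max_{r != 0} | F[ E'_n* E'_m ](r) | ,
        E'_n = sum_m U[n, m] E_m,

   is maximal when each pair of transformed fields differs by a single
   tilt, i.e. when the unitary retrieval ambiguity is undone. `M` is
   ascended over U(N) by projected gradient steps (the arg-max pixel of
   each pair held fixed within a step), polar retraction back to the
   unitary manifold, backtracking step halving, and seeded random
   restarts in addition to the identity start — so the final metric
   never falls below `M(I)`. The pairwise maps of the *unmixed* fields
   are precomputed once (`G(U) = conj(U) B U^T` per pixel), making each
   metric/gradient evaluation independent of the pixel data.

   For 3D objects the pairwise phase is quadratic rather than linear and
   the global metric blurs; demixing then runs on a 3×3 grid of
   cosine-tapered, 25%-overlapping tiles, where the quadratic phase is
   locally linear. A tile can only demix sources it actually sees:
   fields carrying a few percent of a tile's energy are unconstrained
   there, which is why tiles overlap and the construction below
   re-matches fields across tiles.

4. **Plane refinement by autofocus** (`model`). The arg-max of `Gamma`
   localizes the layer only to about ±1 µm — the `Gamma(z)` profile is
   broad and its peak wanders with the screen realization — while the
   virtual layer degrades noticeably beyond ~±0.5 µm. Since demixing
   commutes with propagation, the demixed set is swept over ±2 µm
   (0.25 µm step); at each candidate a provisional layer is built and a
   small probe stack reconstructed, and the plane maximizing the probe's
   peak intensity wins. In tiled mode the central tile serves as the
   probe. This step is on by default; the plain correlation arg-max is
   still reported alongside it.

5. **Virtual-layer construction** (`medium`). At the located plane the
   relative phase of a pair is `arg(E_n* E_m) = arg(h_n* h_m)`: a tilt
   for co-planar sources, a quadratic for sources at different depths.
   Tilts are fitted by sub-pixel peak location of `F[E_n* E_m]`
   (parabolic interpolation, then three rounds of magnitude-weighted
   phase-gradient refinement); quadratics by weighted least squares on
   the phase *gradients* of the smoothed product (Gaussian σ = 2 px), an
   unwrap-free formulation. Construction is incremental: the
   best-correlated pair seeds a running coherent sum (the higher-energy
   member is the reference, fixing the overall phase), and remaining
   fields are admitted in order of their correlation against the current
   sum; candidates below an admission threshold (default 0.1, normalized
   score) are excluded and listed. The layer is

        S(r) = exp( i arg[ sum_n E_n e^{i Phi_n} ] ),

   phase-only by construction — the compensation needs only phase, and
   an amplitude would bias energy. `S` carries the phase of
   `S_o h_ref`, not `S_o` alone: the reference field's own free-space
   phase is an inherent, harmless ambiguity (it maps the reconstruction
   into a shifted/scaled frame; see calibration).

   Tiled mode builds one layer per tile. Because each tile picks its own
   reference, tiles are first re-matched through their mixing matrices
   (Hungarian assignment on `|U_t U_c*|` against the central tile) so
   all share approximately one reference, then blended with the
   cosine-taper weights after removing a best-fit tilt-plus-offset
   between each new tile and the growing mosaic (references of co-planar
   sources differ by a tilt, so a constant offset alone is not enough).

6. **Reconstruction and evaluation** (`reconstruct`, `evaluate`). The
   holographic image is

        I(r, z) = sum_n | P_z{ F[ E_n* S ] }(r) |^2 ,

   invariant under any unitary mixture of the field set (so the
   undemixed set can be used once `S` exists). The stack lives in a
   synthetic frame: a demagnified (factor ≈ N·pitch²/(λZ) for sources at
   depth Z), possibly mirrored copy of object space with its own z
   scale. Sources are detected as 3D local maxima above a relative
   threshold, sub-pixel refined by 3-point quadratic fits and merged
   laterally within a small radius. The frame is mapped to object
   micrometres by a fixture-based calibration: scaled Procrustes on
   Hungarian-matched detection/truth pairs over both mirror parities and
   a rotation sweep, plus an independent affine z fit. PSNR/SSIM are
   computed after background subtraction (1st percentile), unit-peak
   normalization and rigid registration by the antisymmetrized sub-pixel
   cross-correlation shift (applied as a periodic Fourier shift, making
   the metric exactly symmetric in its arguments); PSNR is capped at
   100 dB. FWHM is measured on sinc-interpolated (8×) line profiles with
   linear interpolation at half maximum, divided by the calibrated
   magnification.

## Synthetic data: what it emulates and what it does not

The simulator (`simulate`) realises the thin-layer model exactly:
band-limited point-source fields (collection NA 0.35 by default),
multiplied by a Gaussian random phase screen, propagated to the
camera-conjugate plane, modulated per-pixel by i.i.d. uniform phase
masks, and summed incoherently. Optional Poisson shot noise at a stated
photon budget; off by default. All randomness flows from named integer
seeds and runs are bit-reproducible.

Default screen: correlation length 0.9 µm, phase RMS 2.5 rad. This is a
strongly scattering screen in the relevant senses — the unscattered
(ballistic) fraction is `exp(-2.5²) ≈ 0.2 %` and a bead's image at the
camera is an unrecognizable speckle blob — but its angular divergence
(~0.24 NA) is bounded by the sampled band (`na_max = 0.65` at 0.4 µm
pitch), far from the 90°-divergence regime of a ground-glass diffuser.
Consequences: the memory-effect range in the simulator is wider than for
a laboratory diffuser, and passing tests demonstrate correctness of the
estimation chain, not performance under arbitrary scattering strength.

Geometry constraints worth knowing:

* The simulated FOV must contain the deepest source's collection cone
  (diameter ≈ 2·z·tan(asin NA)); on a periodic grid the cone otherwise
  aliases onto itself and the relative-phase estimates break down. The
  bead protocols (sources 80–100 µm deep) therefore use 192×192 px
  (76.8 µm); the spiral protocol uses 128×128 px with a 55 µm base
  depth.
* Reconstructed peak brightness scales with the source's cone area at
  the layer, so sources spanning a depth range reconstruct with unequal
  brightness (ratio ≈ (z_max/z_min)²) on top of a residual
  aberration-mismatch loss that grows with lateral distance from the
  effective reference. The coherent-sum layer (a compromise reference)
  keeps this spread small enough that all twenty spiral foci typically
  clear a half-maximum detection threshold; occasionally (seed
  dependent) one focus lands marginally below it.

Not emulated: fluorophore photophysics (bleaching, blinking), spectral
bandwidth and temporal-coherence effects, volumetric multiple
scattering, camera noise other than shot noise, experimental drift.

## Default parameters

| Parameter | Default | Why |
| --- | --- | --- |
| pitch | 0.4 µm | samples the intensity of an NA-0.35 image (field band 2·NA·k0) |
| wavelength | 0.55 µm | green fluorescence emission |
| collection NA | 0.35 | effective NA of the emulated system |
| grid `na_max` | 0.65 | head-room for the screen's angular divergence; Nyquist-safe at 0.4 µm |
| screen ℓ, σ | 0.9 µm, 2.5 rad | strongly scattering yet within the sampled band (see above) |
| masks | ≥ 10 × sources, macropixel 1 px | conditioning of the retrieval; no count is prescribed by the physics |
| retrieval stop | Δresidual < 1e-9, ≤ 300 epochs | noiseless data converge far below this |
| exclusion disk | 3 px | removes the n = m peak; also used in the demix metric |
| demix | 150 iterations, 2 restarts | metric plateau well before this on all protocols |
| admission threshold | 0.1 | normalized correlation below which a field is excluded |
| tile layout | 3×3, 25 % overlap, cosine taper | quadratic phase locally linear at this tile size |
| detection | 0.5 × max, merge 0.8 µm | half-maximum counting with sub-Rayleigh merge (reconstruction frame) |

## Numerical choices, degenerate inputs, tie-breaks

* Unitary centred FFTs everywhere; zero frequency at the array centre.
* `propagate(·, 0)` is the exact identity; nonzero distances band-limit.
* Retrieval guards pixels with modeled intensity below 1e-30 (left
  unchanged by the amplitude projection); an all-zero measurement stack
  is rejected; more states than masks warns (ill-posed); states ending
  with < 1 % of total energy warn (over-specified N).
* Demix line search halves the step up to 12 times; a step that cannot
  improve the metric terminates that start (subgradient stationarity).
  Pair-map precomputation is single precision — peaks are located, not
  differentiated, and every step is validated on the metric itself.
* The compensated fields are band-limited once before refocusing so the
  stack's total energy is constant across z (unitary propagation).
* Calibration tries both mirror parities and 24 trial rotations, then
  iterates Hungarian matching with scaled-Procrustes refinement; the z
  map degenerates to unit scale and a mean offset when either side
  spans a single depth (flagged `z_degenerate`).
* FWHM measurement climbs to the local peak before bracketing and
  returns NaN (with a warning) if the profile never drops below half
  maximum in the window.

## Known limitations

* Scattering strength is bounded by the sampled band (above); truly
  isotropic diffusers are outside the simulator's reach.
* The brightness non-uniformity across depth is a property of the
  method's geometry, not a bug; detection at a fixed global threshold
  can drop a marginal focus on unlucky realizations.
* Tile-local demixing cannot separate sources a tile barely sees; the
  stitched layer inherits slightly noisier phase near such tiles'
  edges.
* The calibration is fixture-based (it uses the known ground truth of
  the simulated object); mapping reconstructions of unknown objects to
  absolute micrometres requires an external reference, exactly as in a
  real instrument.
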