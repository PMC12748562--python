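"""Unit tests for field correlations, plane location and demixing."""

import numpy as np
import pytest

from holoscat.grids import ComplexField, OpticalGrid
from holoscat.correlation import (TileLayout,
                                  correlation_volume, demix_tiled,
                                  demix_unitary, exclusion_mask,
                                  locate_correlation_plane, pair_tilt_map,
                                  shift_tilt_correlation,
                                  tilt_correlation_map)
from holoscat.retrieval import RetrievedFieldSet

from conftest import haar_unitary, random_field_values


def _small_grid(n=16):
    return OpticalGrid(n_x=n, n_y=n, pitch=0.4, wavelength=0.55, na_max=0.4)


def _brute_force_correlation(e_n, e_m, grid, shift, tilt):
    """Independent oracle: explicit DFT interpolation + double-loop sum."""
    ny, nx = grid.shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=grid.pitch)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=grid.pitch)
    spec = np.fft.fft2(e_n)
    c = 0.0 + 0.0j
    for iy in range(ny):
        for ix in range(nx):
            # E_n evaluated at (x - sx, y - sy) by direct Fourier synthesis
            val = 0.0 + 0.0j
            x = (ix - nx // 2) * grid.pitch
            y = (iy - ny // 2) * grid.pitch
            for jy in range(ny):
                for jx in range(nx):
                    # spatial coordinate measured from pixel (0, 0) to match
                    # the plain fft2 convention used for `spec`
                    px = ix * grid.pitch - shift[0]
                    py = iy * grid.pitch - shift[1]
                    val += spec[jy, jx] * np.exp(
                        1j * (kx[jx] * px + ky[jy] * py))
            val /= nx * ny
            c += val * np.conj(e_m[iy, ix]) * np.exp(
                1j * (tilt[0] * x + tilt[1] * y))
    return c


class TestShiftTiltCorrelation:
    def test_self_correlation_is_energy(self, grid64):
        f = ComplexField(random_field_values(grid64, 0), grid64)
        c = shift_tilt_correlation(f, f)
        assert c.imag == pytest.approx(0.0, abs=1e-9 * abs(c))
        assert c.real == pytest.approx(f.energy, rel=1e-12)

    def test_matched_filter_peaks_at_true_shift(self, grid64):
        vals = random_field_values(grid64, 1, band_limited=True)
        # a(x) = vals(x - pitch): recovering vals requires shift = -pitch
        a = ComplexField(np.roll(vals, 1, axis=1), grid64)
        b = ComplexField(vals, grid64)
        c_true = abs(shift_tilt_correlation(a, b, shift=(-grid64.pitch, 0.0)))
        assert c_true == pytest.approx(b.energy, rel=1e-9)
        for other in [(0.0, 0.0), (grid64.pitch, 0.0), (0.0, -grid64.pitch)]:
            assert abs(shift_tilt_correlation(a, b, shift=other)) < c_true

    def test_matches_brute_force_oracle(self):
        """FFT/Fourier-interpolation path vs explicit double-loop sum."""
        grid = _small_grid(16)
        e_n = random_field_values(grid, 2)
        e_m = random_field_values(grid, 3)
        a = ComplexField(e_n, grid)
        b = ComplexField(e_m, grid)
        rng = np.random.default_rng(4)
        for _ in range(20):
            shift = tuple(rng.uniform(-1.5, 1.5, 2))
            tilt = tuple(rng.uniform(-2.0, 2.0, 2))
            fast = shift_tilt_correlation(a, b, shift, tilt)
            slow = _brute_force_correlation(e_n, e_m, grid, shift, tilt)
            assert abs(fast - slow) < 1e-10 * max(abs(slow), 1.0)

    def test_shift_beyond_grid_rejected(self, grid64):
        f = ComplexField(random_field_values(grid64, 5), grid64)
        with pytest.raises(ValueError, match="extent"):
            shift_tilt_correlation(f, f, shift=(1e4, 0.0))


class TestTiltMap:
    def test_on_grid_tilt_gives_exact_peak(self, grid64):
        vals = random_field_values(grid64, 6, band_limited=True)
        k0x = grid64.kx[grid64.n_x // 2 + 5]
        tilted = vals * np.exp(1j * k0x * grid64.xx)
        cmap = pair_tilt_map(vals, tilted)
        iy, ix = np.unravel_index(np.argmax(np.abs(cmap)), cmap.shape)
        assert ix == grid64.n_x // 2 + 5
        assert iy == grid64.n_y // 2

    def test_cauchy_schwarz_bound(self, grid64):
        a = random_field_values(grid64, 7)
        b = random_field_values(grid64, 8)
        cmap = np.abs(pair_tilt_map(a, b))
        bound = np.linalg.norm(a) * np.linalg.norm(b) / np.sqrt(a.size)
        assert cmap.max() <= bound * (1 + 1e-12)

    def test_geometric_tilt_of_displaced_sources(self, small_scene,
                                                 truth_fields):
        """Two sources dx apart at depth Z differ at the layer by a tilt
        k0*dx/Z, visible as the pair-map peak position."""
        grid = small_scene["grid"]
        at_layer = truth_fields.propagate_to(30.0)
        src = small_scene["sources"]
        cmap = np.abs(pair_tilt_map(at_layer.values[0], at_layer.values[1]))
        iy, ix = np.unravel_index(np.argmax(cmap), cmap.shape)

        def _para(vm, v0, vp):
            den = vm - 2 * v0 + vp
            return 0.5 * (vm - vp) / den if den < 0 else 0.0

        fx = ix + _para(cmap[iy, ix - 1], cmap[iy, ix], cmap[iy, ix + 1])
        fy = iy + _para(cmap[iy - 1, ix], cmap[iy, ix], cmap[iy + 1, ix])
        dk_bin = grid.kx[1] - grid.kx[0]
        k_meas = np.array([grid.kx[0] + fx * dk_bin,
                           grid.ky[0] + fy * dk_bin])
        dx = np.array([src.x[0] - src.x[1], src.y[0] - src.y[1]])
        k_pred = grid.k0 * dx / 30.0
        assert np.all(np.abs(k_meas - k_pred) <= dk_bin)

    def test_full_map_shape(self, truth_fields):
        maps = tilt_correlation_map(truth_fields)
        assert maps.shape == (3, 3) + truth_fields.grid.shape


class TestCorrelationVolume:
    def test_gamma_nonnegative_and_quartic(self, truth_fields):
        vol = correlation_volume(truth_fields, [25.0, 30.0, 35.0])
        assert np.all(vol.values >= 0)
        doubled = RetrievedFieldSet(values=2.0 * truth_fields.values,
                                    grid=truth_fields.grid)
        vol2 = correlation_volume(doubled, [25.0, 30.0, 35.0])
        assert np.allclose(vol2.values, 16.0 * vol.values, rtol=1e-9)

    def test_single_field_rejected(self, truth_fields):
        one = RetrievedFieldSet(values=truth_fields.values[:1],
                                grid=truth_fields.grid)
        with pytest.raises(ValueError, match="two fields"):
            correlation_volume(one, [0.0, 1.0])

    def test_locates_screen_within_one_step(self, truth_fields):
        """The layer sits 30 um from the camera focal plane; the masked
        correlation maximum finds it on a 2-um grid."""
        vol = correlation_volume(truth_fields, np.arange(14.0, 46.1, 2.0))
        loc = locate_correlation_plane(vol)
        assert abs(loc.z_hat - 30.0) <= 2.0
        assert loc.localized

    def test_reversed_candidates_same_answer(self, truth_fields):
        zs = np.arange(14.0, 46.1, 2.0)
        a = locate_correlation_plane(correlation_volume(truth_fields, zs))
        b = locate_correlation_plane(
            correlation_volume(truth_fields, zs[::-1]))
        assert a.z_hat == b.z_hat

    def test_exclusion_disk_removes_autocorrelation(self, grid64):
        """For identical fields the r=0 bin dominates; the mandated
        exclusion makes the off-centre structure decide instead."""
        vals = random_field_values(grid64, 9, band_limited=True)
        pair = RetrievedFieldSet(values=np.stack([vals, vals]), grid=grid64)
        vol0 = correlation_volume(pair, [0.0, 5.0], exclusion_radius=0)
        mask0 = exclusion_mask(grid64.shape, 0)
        # radius 0 keeps the centre bin, which wins trivially
        centre = vol0.values[0][grid64.n_y // 2, grid64.n_x // 2]
        assert centre == vol0.values[0].max()
        vol3 = correlation_volume(pair, [0.0, 5.0], exclusion_radius=3)
        loc3 = locate_correlation_plane(vol3)
        masked = vol0.values * exclusion_mask(grid64.shape, 3)[None]
        expected = float(vol0.z_values[np.argmax(masked.max(axis=(1, 2)))])
        assert loc3.z_hat == expected


class TestDemixUnitary:
    def _tilt_set(self, grid, n=3, seed=0):
        """Already-demixed fields: common random screen x distinct tilts."""
        rng = np.random.default_rng(seed)
        screen = np.exp(1j * rng.uniform(0, 2 * np.pi, grid.shape))
        fields = []
        for i in range(n):
            # tilt spacing well outside the 3-px exclusion disk of the metric
            kx = grid.kx[grid.n_x // 2 + 6 * (i + 1)]
            fields.append(screen * np.exp(1j * kx * grid.xx))
        return RetrievedFieldSet(values=np.array(fields), grid=grid)

    def test_already_demixed_is_fixed_point(self, grid64):
        fields = self._tilt_set(grid64)
        mixing, _ = demix_unitary(fields, seed=0, max_iters=100, n_restarts=2)
        assert mixing.metric_value <= mixing.metric_identity * 1.01
        # U is a permutation times diagonal phases: one dominant entry
        # per row/column
        mags = np.abs(mixing.matrix)
        assert np.all(mags.max(axis=1) > 0.97)
        assert np.all(mags.max(axis=0) > 0.97)

    def test_unitarity_maintained(self, grid64):
        fields = self._tilt_set(grid64).mixed_by(haar_unitary(3, 1))
        mixing, _ = demix_unitary(fields, seed=1, max_iters=500, n_restarts=2)
        assert mixing.unitarity_error < 1e-8

    def test_known_mixture_recovered(self, grid64):
        """Mixing by a known V is undone up to phases and permutation."""
        clean = self._tilt_set(grid64, n=2, seed=2)
        v = haar_unitary(2, 3)
        mixed = clean.mixed_by(v)
        mixing, demixed = demix_unitary(mixed, seed=2, max_iters=300,
                                        n_restarts=3)
        w = mixing.matrix @ v  # should be phase-diagonal times permutation
        mags = np.abs(w) ** 2
        off = 1.0 - mags.max(axis=1)  # residual off-dominant energy per row
        assert np.all(off < 0.05)

    def test_metric_never_below_identity(self, grid64):
        for seed in range(3):
            fields = RetrievedFieldSet(
                values=np.stack([random_field_values(grid64, 10 + seed + i)
                                 for i in range(3)]), grid=grid64)
            mixing, _ = demix_unitary(fields, seed=seed, max_iters=30,
                                      n_restarts=1)
            assert mixing.metric_value >= mixing.metric_identity - 1e-12

    def test_intensity_sum_invariant_under_unitary(self, truth_fields):
        u = haar_unitary(3, 5)
        mixed = truth_fields.mixed_by(u)
        assert np.allclose(np.sum(np.abs(mixed.values) ** 2, axis=0),
                           np.sum(np.abs(truth_fields.values) ** 2, axis=0),
                           rtol=1e-10)

    def test_metric_invariant_under_phases_and_permutation(self, grid64):
        from holoscat.correlation import _pair_peaks, exclusion_mask
        from holoscat.correlation import pair_tilt_map

        fields = self._tilt_set(grid64).mixed_by(haar_unitary(3, 6))
        n = 3
        npix = grid64.n_x * grid64.n_y
        bmaps = np.empty((n, n, npix), dtype=np.complex64)
        for a in range(n):
            for b in range(n):
                bmaps[a, b] = pair_tilt_map(fields.values[a],
                                            fields.values[b]).ravel()
        mask = exclusion_mask(grid64.shape, 3).ravel()
        u = haar_unitary(3, 7)
        m0, _, _ = _pair_peaks(u, bmaps, mask)
        rng = np.random.default_rng(8)
        phases = np.diag(np.exp(1j * rng.uniform(0, 2 * np.pi, 3)))
        perm = np.eye(3)[[2, 0, 1]]
        m1, _, _ = _pair_peaks(phases @ perm @ u, bmaps, mask)
        assert m1 == pytest.approx(m0, rel=1e-5)

    def test_matches_exhaustive_2x2_search(self):
        """Optimizer vs brute-force sweep of the 2x2 unitary quotient
        (rotation angle x relative phase; diagonal phases and permutations
        leave the metric unchanged)."""
        grid = _small_grid(16)
        rng = np.random.default_rng(9)
        screen = np.exp(1j * rng.uniform(0, 2 * np.pi, grid.shape))
        e1 = screen * np.exp(1j * grid.kx[10] * grid.xx)
        e2 = screen * np.exp(1j * grid.ky[11] * grid.yy)
        mixed = RetrievedFieldSet(values=np.array([e1, e2]),
                                  grid=grid).mixed_by(haar_unitary(2, 10))
        from holoscat.correlation import _pair_peaks, exclusion_mask
        from holoscat.correlation import pair_tilt_map

        bmaps = np.empty((2, 2, 256), dtype=np.complex64)
        for a in range(2):
            for b in range(2):
                bmaps[a, b] = pair_tilt_map(mixed.values[a],
                                            mixed.values[b]).ravel()
        mask = exclusion_mask(grid.shape, 3).ravel()
        best = -np.inf
        for theta in np.linspace(0, np.pi / 2, 46):
            c, s = np.cos(theta), np.sin(theta)
            for phi in np.linspace(0, 2 * np.pi, 73):
                u = np.array([[c, s * np.exp(1j * phi)],
                              [-s * np.exp(-1j * phi), c]])
                m, _, _ = _pair_peaks(u, bmaps, mask)
                best = max(best, m)
        mixing, _ = demix_unitary(mixed, seed=3, max_iters=300, n_restarts=5)
        assert mixing.metric_value >= best * 0.99


class TestTileLayout:
    def test_full_coverage_3x3(self):
        layout = TileLayout(3, 3, 0.25)
        covered = np.zeros((128, 128), dtype=int)
        for tile in layout.windows((128, 128)):
            covered[tile["sly"], tile["slx"]] += 1
        assert covered.min() >= 1

    def test_overlap_fraction_roughly_honoured(self):
        layout = TileLayout(3, 3, 0.25)
        tiles = layout.windows((128, 128))
        a, b = tiles[0], tiles[1]  # horizontally adjacent
        overlap = a["slx"].stop - b["slx"].start
        size = a["slx"].stop - a["slx"].start
        assert overlap / size == pytest.approx(0.25, abs=0.05)

    def test_positive_weights_everywhere(self):
        layout = TileLayout(2, 2, 0.3)
        total = np.zeros((64, 64))
        for tile in layout.windows((64, 64)):
            total[tile["sly"], tile["slx"]] += tile["weight"]
        assert total.min() > 0

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            TileLayout(0, 3)
        with pytest.raises(ValueError):
            TileLayout(2, 2, overlap=1.0)


class TestDemixTiled:
    def test_single_tile_equals_global(self, grid64):
        rng = np.random.default_rng(11)
        screen = np.exp(1j * rng.uniform(0, 2 * np.pi, grid64.shape))
        fields = RetrievedFieldSet(values=np.array([
            screen * np.exp(1j * grid64.kx[36] * grid64.xx),
            screen * np.exp(1j * grid64.ky[38] * grid64.yy)]),
            grid=grid64).mixed_by(haar_unitary(2, 12))
        layout = TileLayout(1, 1)
        results = demix_tiled(fields, layout, seed=4, max_iters=100,
                              n_restarts=2)
        assert len(results) == 1
        tile_seed = int(np.random.SeedSequence(4).spawn(1)[0]
                        .generate_state(1)[0] % (2 ** 31))
        mixing, demixed = demix_unitary(fields, seed=tile_seed,
                                        max_iters=100, n_restarts=2)
        assert np.allclose(results[0].mixing.matrix, mixing.matrix)
        assert np.allclose(results[0].demixed.values, demixed.values)

    def test_too_small_tiles_rejected(self, grid64):
        fields = RetrievedFieldSet(
            values=np.stack([random_field_values(grid64, 13 + i)
                             for i in range(2)]), grid=grid64)
        with pytest.raises(ValueError, match="16x16"):
            demix_tiled(fields, TileLayout(8, 8, 0.0), seed=0)

    def test_tiled_agrees_with_global_for_coplanar(self, small_scene,
                                                   truth_fields):
        """For a 2D object the tilt structure is globally linear, so tiled
        and global demixing agree on tile interiors — for every source a
        tile actually sees (a field carrying a small fraction of a tile's
        energy is unconstrained within that tile)."""
        at_layer = truth_fields.propagate_to(30.0)
        mixed = at_layer.mixed_by(haar_unitary(3, 14))
        _, glob = demix_unitary(mixed, seed=5, max_iters=300, n_restarts=5)
        checked = 0
        for tile in demix_tiled(mixed, TileLayout(2, 2, 0.3), seed=5,
                                max_iters=300, n_restarts=5):
            tv = tile.demixed.values.reshape(3, -1)
            gv = (glob.values[:, tile.sly, tile.slx]
                  * tile.weight[None]).reshape(3, -1)
            norms = np.linalg.norm(gv, axis=1)
            strong = norms ** 2 >= 0.15 * np.sum(norms ** 2)
            corr = np.abs(gv.conj() @ tv.T)
            corr /= (norms[:, None] * np.linalg.norm(tv, axis=1)[None, :]
                     + 1e-30)
            # each well-represented global field matches one tile field
            assert np.all(corr.max(axis=1)[strong] > 0.95)
            checked += int(strong.sum())
        assert checked >= 8  # most (tile, field) pairs are actually tested
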