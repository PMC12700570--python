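"""Reconstruction pipeline: demultiplexing, inverse filtering, axial unmixing,
end-to-end round trips and the dense-operator oracle."""

import numpy as np
import pytest

from fsc3d import (
    ChannelImageStack,
    CrosstalkModel,
    DeconvParams,
    InstrumentConfig,
    ReconParams,
    ScatterScene,
    USpectrum,
    Volume3D,
    VoxelGridSpec,
    build_dense_operator,
    build_U,
    compensate_flow_speed,
    deconvolve_x,
    demultiplex,
    dense_reconstruct,
    detect_peaks,
    grid_phantom,
    invert_axial,
    load_volume,
    match_peaks,
    reconstruct_volume,
    resample_volume,
    save_volume,
    simulate,
    threshold_volume,
)
from fsc3d.forward_sim import PMTRecord
from fsc3d.errors import (
    InstabilityError,
    InsufficientDataError,
    SingularityError,
    ValidationError,
)


def _record_of_scans(config, crosstalk, n_scans, fractional=0.0):
    n = int((n_scans + fractional) * config.samples_per_scan)
    return PMTRecord(
        signals=np.zeros((config.n_channels, n)),
        sample_rate=config.sample_rate,
        t0=0.0,
        y_start=0.0,
        config=config,
        crosstalk=crosstalk,
    )


class TestDemultiplex:
    def test_partial_trailing_scan_discarded(self, config, diagonal_crosstalk):
        rec = _record_of_scans(config, diagonal_crosstalk, 10, fractional=0.5)
        stack = demultiplex(rec, config)
        assert stack.n_y == 10

    def test_pixel_sizes_from_printed_constants(self, config, diagonal_crosstalk):
        stack = demultiplex(_record_of_scans(config, diagonal_crosstalk, 4), config)
        assert stack.pixel_size_y == pytest.approx(0.8)  # 0.16 m/s x 5 us
        assert stack.pixel_size_x == pytest.approx(40.0 / 64)

    def test_mid_scan_sample_is_the_zero_column(self, config, diagonal_crosstalk):
        rec = _record_of_scans(config, diagonal_crosstalk, 3)
        s = config.samples_per_scan
        rec.signals[0, s + s // 2] = 1.0  # scan 1, mid-scan sample
        stack = demultiplex(rec, config)
        row, col = np.unravel_index(stack.images[0].argmax(), stack.images[0].shape)
        assert (row, col) == (1, s // 2)
        assert stack.origin[0] + col * stack.pixel_size_x == pytest.approx(0.0)

    def test_fewer_than_two_scans_rejected(self, config, diagonal_crosstalk):
        rec = _record_of_scans(config, diagonal_crosstalk, 1, fractional=0.9)
        with pytest.raises(InsufficientDataError):
            demultiplex(rec, config)


class TestDeconvolveX:
    def _stack(self, images, dx):
        return ChannelImageStack(images, dx, 0.8, (0.0, 0.0))

    def test_vanishing_waist_is_identity(self, rng):
        img = rng.uniform(0, 1, (2, 4, 32))
        out = deconvolve_x(self._stack(img, 0.625), 1e-9)
        np.testing.assert_allclose(out.images, img, rtol=1e-12, atol=1e-12)

    def test_peak_sharpens_at_least_threefold(self):
        n_x, dx, w = 128, 0.375, 3.0
        xg = dx * np.arange(n_x)
        row = np.exp(-2 * (xg - xg[64]) ** 2 / w**2)  # blurred impulse

        def fwhm(r):
            r = r / r.max()
            i = int(np.argmax(r))
            left = next(
                j - 1 + (0.5 - r[j - 1]) / (r[j] - r[j - 1])
                for j in range(i, 0, -1) if r[j - 1] < 0.5
            )
            right = next(
                j + (r[j] - 0.5) / (r[j] - r[j + 1])
                for j in range(i, n_x - 1) if r[j + 1] < 0.5
            )
            return (right - left) * dx

        stack = self._stack(np.tile(row, (1, 2, 1)), dx)
        dec = deconvolve_x(stack, w, DeconvParams(epsilon=1e-12, max_gain=1e9))
        assert fwhm(row) / fwhm(dec.images[0, 0]) >= 3.0

    def test_merged_impulse_pair_separates(self):
        n_x, dx, w = 128, 0.375, 3.0
        xg = dx * np.arange(n_x)
        row = (
            np.exp(-2 * (xg - xg[60]) ** 2 / w**2)
            + np.exp(-2 * (xg - xg[60] - w) ** 2 / w**2)
        )

        def n_maxima(r):
            inner = (r[1:-1] > r[:-2]) & (r[1:-1] >= r[2:]) & (r[1:-1] > 0.2 * r.max())
            return int(inner.sum())

        assert n_maxima(row) == 1  # merged before deconvolution
        stack = self._stack(np.tile(row, (1, 2, 1)), dx)
        dec = deconvolve_x(stack, w, DeconvParams(epsilon=1e-8, max_gain=1e6))
        assert n_maxima(dec.images[0, 0]) == 2

    def test_exact_inverse_refused_on_broadband_input(self, rng):
        img = np.zeros((1, 2, 64))
        img[0, :, 32] = 1.0  # a delta occupies every frequency
        with pytest.raises(InstabilityError):
            deconvolve_x(self._stack(img, 0.625), 3.0, DeconvParams(epsilon=0.0))

    def test_clip_negative(self, rng):
        img = rng.uniform(0, 1, (1, 2, 64))
        out = deconvolve_x(
            self._stack(img, 0.625), 3.0, DeconvParams(clip_negative=True)
        )
        assert np.all(out.images >= 0.0)


class TestBuildU:
    def test_diagonal_closed_form(self):
        w, dy, n = 3.0, 0.8, 128
        u = build_U(CrosstalkModel(mode="diagonal"), w, y_window=n * dy, n_y=n,
                    n_channels=3)
        expected = w * np.sqrt(np.pi / 2) * np.exp(
            -0.5 * np.pi**2 * w**2 * u.ky_grid**2
        )
        assert np.abs(u.values[:, 0, 0] - expected).max() < 1e-6
        off = u.values.copy()
        off[:, range(3), range(3)] = 0.0
        assert np.abs(off).max() == 0.0

    def test_zero_coupling_gives_zero_spectrum(self):
        y_grid = np.linspace(-30, 30, 61)
        zero = CrosstalkModel(mode="tabulated", table=np.zeros((2, 2, 61)), y_grid=y_grid)
        u = build_U(zero, 3.0, y_window=51.2, n_y=64)
        assert np.abs(u.values).max() == 0.0

    def test_dc_term_equals_quadrature(self):
        w, dy, n = 3.0, 0.8, 128
        u = build_U(CrosstalkModel(mode="nearest_neighbor", epsilon=0.25), w,
                    y_window=n * dy, n_y=n, n_channels=4)
        y = (np.arange(n) - n // 2) * dy
        integral = np.trapezoid(np.exp(-2 * y**2 / w**2), dx=dy)
        assert u.values[0, 1, 2].real == pytest.approx(0.25 * integral, rel=1e-9)
        assert u.values[0, 1, 1].real == pytest.approx(integral, rel=1e-9)

    def test_window_must_cover_beam(self):
        with pytest.raises(ValidationError):
            build_U(CrosstalkModel(), 3.0, y_window=10.0, n_y=16, n_channels=2)


class TestInvertAxial:
    def test_diagonal_single_plane_stays_on_plane(self, config, diagonal_crosstalk):
        z3 = config.z_planes[3]
        scene = ScatterScene([[0.0, 10.0, z3]], [1.0], [[0, 0], [10, 10], [z3, z3]])
        rec = simulate(scene, config, diagonal_crosstalk, y_motion="frozen")
        vol = reconstruct_volume(rec, params=ReconParams(
            deconv=DeconvParams(epsilon=1e-10), ridge=0.0))
        peak = vol.intensities[3].max()
        others = np.delete(vol.intensities, 3, axis=0)
        assert np.abs(others).max() < 1e-9 * peak

    def test_recovers_fabricated_spectra(self, rng):
        """V fabricated as U F for known F: the per-k_y solver returns F."""
        nky, nch, nx, dy = 32, 4, 6, 0.8
        uv = np.eye(nch)[None] + 0.3 * rng.normal(size=(nky, nch, nch))
        for q in range(1, nky // 2):  # U(-ky) = conj(U(ky)): real image domain
            uv[nky - q] = uv[q]
        u = USpectrum(values=uv.astype(complex), ky_grid=np.fft.fftfreq(nky, dy),
                      dy=dy, w=3.0)
        f_true = rng.uniform(0, 1, (nch, nky, nx))
        f_hat = np.fft.fft(f_true, axis=1)
        v_hat = np.stack([uv[q] @ f_hat[:, q, :] for q in range(nky)], axis=1)
        v = np.fft.ifft(v_hat, axis=1).real
        vol = invert_axial(ChannelImageStack(v, 1.0, dy, (0, 0)), u, ridge=1e-12)
        rec = vol.intensities / dy  # fabricated directly in spectral units
        assert np.linalg.norm(rec - f_true) / np.linalg.norm(f_true) < 1e-6

    def test_singular_spectrum_without_ridge(self):
        nky, nch = 16, 3
        uv = np.repeat(np.eye(nch)[None], nky, axis=0).astype(complex)
        uv[5] = 0.0  # singular at one frequency
        u = USpectrum(values=uv, ky_grid=np.fft.fftfreq(nky, 0.8), dy=0.8, w=3.0)
        stack = ChannelImageStack(np.zeros((nch, nky, 4)), 1.0, 0.8, (0, 0))
        with pytest.raises(SingularityError, match="k_y"):
            invert_axial(stack, u, ridge=0.0)

    def test_ghost_suppressed_below_two_percent(self, config):
        """Nearest-neighbor coupling 0.3 on a one-plane impulse: raw neighbor
        channel carries ~30% ghost; after inversion < 2% of the true peak."""
        ct = CrosstalkModel(mode="nearest_neighbor", epsilon=0.3)
        z4 = config.z_planes[4]
        scene = ScatterScene([[1.0, 8.0, z4]], [1.0], [[1, 1], [8, 8], [z4, z4]])
        rec = simulate(scene, config, ct)
        stack = demultiplex(rec, config)
        raw_ghost = stack.images[3].max() / stack.images[4].max()
        assert raw_ghost == pytest.approx(0.3, rel=1e-6)
        # noiseless data: bare per-k_y inverse, as in the reconstruction formula
        vol = reconstruct_volume(rec, params=ReconParams(ridge=0.0))
        clipped = np.clip(vol.intensities, 0, None)
        true_peak = clipped[4].max()
        ghost = np.delete(clipped, 4, axis=0).max()
        assert ghost / true_peak < 0.02


class TestFullPipeline:
    def test_sixteen_center_round_trip(self, config, nn_crosstalk):
        """2 centers on each of 8 planes: every center is recovered within one
        voxel laterally and on exactly the right plane."""
        scene = grid_phantom(2, 8, xy_extent=20.0, min_separation=5.0, seed=3)
        rec = simulate(scene, config, nn_crosstalk)
        vol = reconstruct_volume(rec)
        peaks = detect_peaks(vol, threshold=0.5, min_separation=1.5)
        report = match_peaks(peaks, scene, max_dist=2.0)
        assert report.recall == 1.0 and report.precision == 1.0
        voxel_diag = np.hypot(vol.voxel_size[1], vol.voxel_size[2])
        for i, j in report.matches:
            dz = abs(peaks.positions[i, 2] - scene.positions[j, 2])
            dxy = np.linalg.norm(peaks.positions[i, :2] - scene.positions[j, :2])
            assert dz < 1e-9  # exact plane
            assert dxy <= voxel_diag

    def test_empty_record_gives_zero_volume(self, config, diagonal_crosstalk):
        rec = _record_of_scans(config, diagonal_crosstalk, 40)
        vol = reconstruct_volume(rec)
        assert np.all(vol.intensities == 0.0)

    def test_intensity_rank_preserved_per_plane(self, config, nn_crosstalk):
        from fsc3d import integrated_amplitude

        scene = grid_phantom(5, 8, xy_extent=24.0, min_separation=6.0,
                             intensities=(1, 2, 3, 4, 5), seed=1)
        rec = simulate(scene, config, nn_crosstalk)
        vol = reconstruct_volume(rec)
        peaks = detect_peaks(vol, threshold=0.05, min_separation=2.0)
        report = match_peaks(peaks, scene, max_dist=2.0)
        assert report.recall == 1.0
        for z in config.z_planes:
            idx = [(i, j) for i, j in report.matches
                   if abs(scene.positions[j, 2] - z) < 1e-9]
            amps = np.array([integrated_amplitude(vol, peaks.positions[i])
                             for i, _ in idx])
            truth = np.array([scene.intensities[j] for _, j in idx])
            assert np.array_equal(np.argsort(amps), np.argsort(truth))

    def test_pipeline_linearity(self, config, nn_crosstalk):
        s1 = grid_phantom(1, 4, xy_extent=14, seed=5)
        s2 = grid_phantom(1, 4, xy_extent=14, seed=6)
        kw = dict(duration=3.5e-4, y_start=-20.0)
        r1 = simulate(s1, config, nn_crosstalk, **kw)
        r2 = simulate(s2, config, nn_crosstalk, **kw)
        mix = PMTRecord(2.0 * r1.signals + 0.5 * r2.signals, r1.sample_rate,
                        0.0, r1.y_start, config, nn_crosstalk)
        v_mix = reconstruct_volume(mix)
        v1 = reconstruct_volume(r1)
        v2 = reconstruct_volume(r2)
        lhs = v_mix.intensities
        rhs = 2.0 * v1.intensities + 0.5 * v2.intensities
        assert np.abs(lhs - rhs).max() <= 1e-9 * np.abs(rhs).max()

    def test_shift_equivariance_along_flow(self, config, nn_crosstalk):
        scene = grid_phantom(1, 4, xy_extent=14, seed=7)
        m = 5  # delay by m scan periods
        shifted = scene.shifted(dy=m * config.pixel_size_y)
        kw = dict(duration=4.0e-4, y_start=-20.0)
        v0 = reconstruct_volume(simulate(scene, config, nn_crosstalk,
                                         y_motion="frozen", **kw))
        v1 = reconstruct_volume(simulate(shifted, config, nn_crosstalk,
                                         y_motion="frozen", **kw))
        a = v0.intensities[:, 10:-15, :]
        b = v1.intensities[:, 10 + m:v1.intensities.shape[1] - 15 + m, :]
        assert np.abs(a - b).max() <= 1e-9 * np.abs(a).max()

    def test_oracle_equivalence_on_small_grid(self, small_config, nn_crosstalk, rng):
        """FFT pipeline vs dense Tikhonov least squares on a 12x12x4 grid."""
        cfg = small_config
        dx, dy = cfg.pixel_size_x, cfg.pixel_size_y
        grid = VoxelGridSpec(
            -cfg.scan_range / 2 + dx * np.arange(2, 14), dy * np.arange(12),
            cfg.z_planes,
        )
        vals = rng.uniform(0, 1, grid.n_voxels)
        scene = grid.scene(vals)
        dur = (scene.y_span() + 8 * cfg.beam_waist_w) / (cfg.flow_speed_vy * 1e6)
        y0 = float(np.floor((-4 * cfg.beam_waist_w) / dy) * dy)
        rec = simulate(scene, cfg, nn_crosstalk, duration=dur,
                       y_motion="frozen", y_start=y0)
        a = build_dense_operator(grid, cfg, nn_crosstalk, dur, y_start=y0)
        f_dense = dense_reconstruct(a, rec.signals, ridge=1e-10).reshape(grid.shape)
        vol = reconstruct_volume(
            rec, params=ReconParams(deconv=DeconvParams(epsilon=1e-10), ridge=1e-10)
        )
        row0 = int(round((0.0 - rec.y_start) / dy))
        sub = vol.intensities[:, row0:row0 + 12, 2:14]
        rel = np.linalg.norm(sub - f_dense) / np.linalg.norm(f_dense)
        assert rel <= 1e-4

    @pytest.mark.parametrize("eps", [0.1, 0.2, 0.3])
    def test_crosstalk_suppression_monotone(self, config, eps):
        from fsc3d import crosstalk_suppression

        ct = CrosstalkModel(mode="nearest_neighbor", epsilon=eps)
        z2 = config.z_planes[2]
        scene = ScatterScene([[0.0, 9.0, z2]], [1.0], [[0, 0], [9, 9], [z2, z2]])
        rec = simulate(scene, config, ct)
        report = crosstalk_suppression(
            reconstruct_volume(rec), demultiplex(rec, config), scene
        )
        assert report["before"] == pytest.approx(eps, rel=1e-6)
        assert report["after"] < eps  # strictly suppressed


class TestResample:
    def test_identity_when_shape_unchanged(self, rng):
        vol = Volume3D(rng.uniform(0, 1, (8, 20, 16)), (2.5, 0.8, 0.625), (0, 0, 0))
        out = resample_volume(vol, (8, 20, 16))
        np.testing.assert_allclose(out.intensities, vol.intensities, atol=1e-12)

    def test_standard_display_shape(self, rng):
        from scipy import ndimage

        raw = ndimage.gaussian_filter(rng.uniform(0, 1, (8, 40, 64)), 3)
        vol = Volume3D(raw, (2.5, 0.8, 0.625), (0, 0, 0))
        out = resample_volume(vol, (100, 200, 200))
        assert out.shape == (100, 200, 200)
        # physical extent preserved
        for n_old, n_new, v_old, v_new in zip(vol.shape, out.shape,
                                              vol.voxel_size, out.voxel_size):
            assert n_old * v_old == pytest.approx(n_new * v_new)
        # integrated intensity preserved for a smooth volume
        i_old = vol.intensities.sum() * np.prod(vol.voxel_size)
        i_new = out.intensities.sum() * np.prod(out.voxel_size)
        assert i_new == pytest.approx(i_old, rel=0.01)

    def test_constant_volume_stays_constant(self):
        vol = Volume3D(np.full((4, 6, 8), 2.0), (1, 1, 1), (0, 0, 0))
        out = resample_volume(vol, (8, 12, 16))
        np.testing.assert_allclose(out.intensities, 2.0)

    def test_degenerate_target_rejected(self):
        vol = Volume3D(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValidationError):
            resample_volume(vol, (1, 4, 4))


class TestFlowCompensation:
    def test_identity_at_nominal_speed(self, rng):
        st = ChannelImageStack(rng.uniform(0, 1, (2, 30, 8)), 0.625, 0.8, (0, 0))
        out = compensate_flow_speed(st, 0.16, 0.16)
        np.testing.assert_array_equal(out.images, st.images)

    def test_half_speed_sphere_recovers_aspect_ratio(self):
        """A sphere flowed at 0.08 m/s but demultiplexed assuming 0.16 m/s
        appears distorted 2x along y; compensation restores y/x to 1 +- 0.1."""
        from fsc3d import bead_shell_phantom

        bead = bead_shell_phantom(20.0, n_surface_points=400, seed=1)
        cfg_true = InstrumentConfig(flow_speed_vy=0.08)
        cfg_nominal = InstrumentConfig(flow_speed_vy=0.16)
        rec = simulate(bead, cfg_true)
        mislabeled = PMTRecord(rec.signals, rec.sample_rate, 0.0, rec.y_start,
                               cfg_nominal, rec.crosstalk)
        stack = demultiplex(mislabeled, cfg_nominal)

        def aspect(st):
            img = st.images.sum(axis=0)
            ys, xs = np.where(img > 0.1 * img.max())
            return ((ys.max() - ys.min() + 1) * st.pixel_size_y) / (
                (xs.max() - xs.min() + 1) * st.pixel_size_x
            )

        assert abs(aspect(stack) - 2.0) < 0.3  # distorted before
        comp = compensate_flow_speed(stack, vy_actual=0.08, vy_nominal=0.16)
        assert abs(aspect(comp) - 1.0) <= 0.1

    def test_reciprocal_compensation_round_trips(self):
        yy = np.exp(-((np.arange(120) - 60.0) ** 2) / (2 * 15.0**2))
        img = np.tile(yy[None, :, None], (2, 1, 8))
        st = ChannelImageStack(img, 0.625, 0.8, (0, 0))
        once = compensate_flow_speed(st, 0.9 * 0.16, 0.16)
        back = compensate_flow_speed(once, 0.16 / 0.9, 0.16)
        n = min(back.n_y, st.n_y)
        rel = np.linalg.norm(back.images[:, :n] - st.images[:, :n]) / np.linalg.norm(
            st.images[:, :n]
        )
        assert rel < 1e-3

    def test_nonpositive_speed_rejected(self, rng):
        st = ChannelImageStack(rng.uniform(0, 1, (1, 10, 4)), 1.0, 1.0, (0, 0))
        with pytest.raises(ValidationError):
            compensate_flow_speed(st, 0.0, 0.16)


class TestThreshold:
    def test_zero_level_keeps_everything(self, rng):
        vol = Volume3D(rng.uniform(0.1, 1, (3, 4, 5)), (1, 1, 1), (0, 0, 0))
        mask, masked = threshold_volume(vol, 0.0)
        assert mask.intensities.all()
        np.testing.assert_array_equal(masked.intensities, vol.intensities)

    def test_unit_level_keeps_only_argmax(self, rng):
        data = rng.uniform(0, 0.5, (3, 4, 5))
        data[1, 2, 3] = 1.0
        mask, _ = threshold_volume(Volume3D(data, (1, 1, 1), (0, 0, 0)), 1.0)
        assert mask.intensities.sum() == 1
        assert mask.intensities[1, 2, 3] == 1

    def test_invalid_level(self, rng):
        vol = Volume3D(np.zeros((2, 2, 2)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValidationError):
            threshold_volume(vol, 1.5)

    def test_high_threshold_reveals_surface_beads(self, config, nn_crosstalk):
        """A cell with 4 bright surface beads: thresholding the reconstruction
        at 0.6 shows every bead as its own connected component, plus at most a
        few components from chance clumps of cytoplasmic scatterers."""
        from scipy import ndimage

        from fsc3d import cell_phantom

        cell = cell_phantom(cell_diameter=14.0, n_internal=120, n_beads=4,
                            bead_intensity_ratio=5.0, min_bead_separation=4.0,
                            seed=2)
        rec = simulate(cell, config, nn_crosstalk)
        vol = reconstruct_volume(rec)
        mask, _ = threshold_volume(vol, 0.6)
        labels, n_comp = ndimage.label(mask.intensities, structure=np.ones((3, 3, 3)))
        assert 4 <= n_comp <= 7
        # every bead lands in its own component
        origin = np.asarray(vol.origin)
        voxel = np.asarray(vol.voxel_size)
        bead_labels = set()
        for bx, by, bz in cell.metadata["bead_positions_um"]:
            iz, iy, ix = np.round((np.array([bz, by, bx]) - origin) / voxel).astype(int)
            win = labels[max(0, iz - 1):iz + 2, max(0, iy - 2):iy + 3,
                         max(0, ix - 2):ix + 3]
            hit = set(win[win > 0].ravel())
            assert hit, "bead left no suprathreshold response"
            bead_labels |= hit
        assert len(bead_labels) == 4


class TestVolumeIO:
    def test_ome_tiff_round_trip(self, tmp_path, rng):
        vol = Volume3D(rng.uniform(0, 1, (8, 12, 16)).astype(np.float32),
                       (2.5, 0.8, 0.625), (-8.75, 0.0, -20.0))
        path = save_volume(vol, tmp_path / "v.ome.tiff")
        back = load_volume(path)
        assert back.shape == vol.shape
        np.testing.assert_allclose(back.intensities, vol.intensities, rtol=1e-6)
        np.testing.assert_allclose(back.voxel_size, vol.voxel_size)
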