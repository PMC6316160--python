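"""Map I/O, band extraction, sum-spectrum, I1078, contrasts, band shifts."""
import numpy as np
import pytest

from nanosers import maps as mp
from nanosers import synthetic as syn
from nanosers.maps import (
    CellMask,
    HyperspectralMap,
    MapFormatError,
    MaskError,
    MissingReferenceGroupError,
    Spectrum,
    SpectralAxisError,
    UptakeResult,
    WindowError,
)


def small_map(values: np.ndarray, step=2.0, exposure=3.0) -> HyperspectralMap:
    ny, nx, k = values.shape
    axis = np.linspace(1000.0, 1200.0, k)
    return HyperspectralMap(axis, values, step_um=step, exposure_s=exposure)


class TestContainers:
    def test_axis_must_increase(self):
        with pytest.raises(SpectralAxisError):
            Spectrum(np.array([3.0, 2.0, 1.0]), np.zeros(3))

    def test_exposure_must_be_positive(self):
        with pytest.raises(SpectralAxisError):
            Spectrum(np.arange(3.0), np.zeros(3), exposure_s=0.0)


class TestMapIO:
    def test_round_trip(self, tmp_path, map_spec_factory):
        hmap, _, _ = syn.generate_cell_map(
            "PC3", 2, map_spec_factory(2, nx=5, ny=4, wn_start=1000, wn_stop=1100,
                                       wn_step=10, cell_center=(2.0, 1.5),
                                       cell_semi_axes=(1.5, 1.0)),
        )
        path = tmp_path / "map.tsv"
        mp.write_map(hmap, path)
        back = mp.read_map(path)
        assert back.exposure_s == hmap.exposure_s
        assert back.step_um == pytest.approx(hmap.step_um)
        np.testing.assert_allclose(back.wavenumber, hmap.wavenumber)
        np.testing.assert_allclose(back.intensity, hmap.intensity, rtol=1e-6)

    def test_missing_pixel_named_in_error(self, tmp_path):
        hmap = small_map(np.ones((2, 2, 3)))
        path = tmp_path / "map.tsv"
        mp.write_map(hmap, path)
        lines = path.read_text().splitlines()
        # drop the first spectral row of pixel (x=2, y=0)
        drop = next(
            i for i, l in enumerate(lines) if l.startswith("2\t0\t")
        )
        path.write_text("\n".join(lines[:drop] + lines[drop + 1 :]) + "\n")
        with pytest.raises(MapFormatError, match=r"x=2.*y=0"):
            mp.read_map(path)

    def test_missing_exposure_header(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("x_um\ty_um\twavenumber_cm1\tintensity\n0\t0\t1000\t1\n")
        with pytest.raises(MapFormatError, match="exposure"):
            mp.read_map(path)

    def test_handwritten_fixture_values(self, tmp_path):
        rows = []
        for iy, y in enumerate((0.0, 2.0)):
            for ix, x in enumerate((0.0, 2.0)):
                for iw, w in enumerate((1000.0, 1010.0, 1020.0)):
                    rows.append(f"{x}\t{y}\t{w}\t{iy * 100 + ix * 10 + iw}")
        path = tmp_path / "fixture.tsv"
        path.write_text(
            "# exposure_s: 3\n# step_um: 2\nx_um\ty_um\twavenumber_cm1\tintensity\n"
            + "\n".join(rows) + "\n"
        )
        hmap = mp.read_map(path)
        assert hmap.intensity.shape == (2, 2, 3)
        assert hmap.intensity[1, 0, 2] == 102.0
        assert hmap.intensity[0, 1, 0] == 10.0

    def test_spectrum_round_trip(self, tmp_path):
        s = syn.generate_tp_spectrum("sers", noise_sd=2.0, seed=5)
        path = tmp_path / "s.csv"
        mp.write_spectrum(s, path)
        back = mp.read_spectrum(path)
        assert back.exposure_s == s.exposure_s
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-6)


class TestBandIntensity:
    def test_linear_ramp_is_removed_exactly(self):
        axis = np.arange(1000.0, 1161.0, 2.0)
        s = Spectrum(axis, 0.5 * axis - 100.0, exposure_s=1.0)
        assert mp.band_intensity(s, center=1078, half_window=20) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_pseudo_voigt_height_recovery(self):
        axis = np.arange(900.0, 1300.0, 2.0)
        amp = 37.0
        s = Spectrum(axis, amp * syn.pseudo_voigt(axis, 1078.0, 10.0), exposure_s=1.0)
        h = mp.band_intensity(s, center=1078, half_window=40, mode="height")
        assert h == pytest.approx(amp, rel=0.01)

    def test_exposure_normalization(self):
        axis = np.arange(1000.0, 1161.0, 2.0)
        y = 10.0 * syn.pseudo_voigt(axis, 1078.0, 10.0)
        h1 = mp.band_intensity(Spectrum(axis, y, 1.0))
        h2 = mp.band_intensity(Spectrum(axis, y, 2.0))
        assert h2 == pytest.approx(h1 / 2)

    def test_area_mode_integrates_gaussian_band(self):
        axis = np.arange(900.0, 1300.0, 2.0)
        # pure Gaussian band (eta=0): analytic area = fwhm * sqrt(pi / (4 ln 2))
        s = Spectrum(
            axis, syn.pseudo_voigt(axis, 1078.0, 10.0, eta=0.0), exposure_s=1.0
        )
        area = mp.band_intensity(s, center=1078, half_window=40, mode="area")
        expected = 10.0 * np.sqrt(np.pi / (4 * np.log(2)))
        assert area == pytest.approx(expected, rel=0.02)

    def test_window_outside_axis_rejected(self):
        axis = np.arange(1000.0, 1101.0, 2.0)
        s = Spectrum(axis, np.zeros_like(axis))
        with pytest.raises(WindowError):
            mp.band_intensity(s, center=1090, half_window=20)


class TestReconstructImage:
    def test_uniform_map_constant_image(self):
        axis = np.arange(1000.0, 1161.0, 2.0)
        y = 5.0 * syn.pseudo_voigt(axis, 1078.0, 10.0)
        cube = np.broadcast_to(y, (4, 6, axis.size)).copy()
        img = mp.reconstruct_image(HyperspectralMap(axis, cube, exposure_s=1.0))
        assert img.shape == (4, 6)
        assert np.allclose(img, img[0, 0])

    def test_matches_per_pixel_band_intensity(self, map_spec_factory):
        hmap, _, _ = syn.generate_cell_map("PC3", 2, map_spec_factory(8))
        img = mp.reconstruct_image(hmap)
        for ix, iy in [(0, 0), (14, 15), (29, 29), (7, 22)]:
            assert img[iy, ix] == pytest.approx(
                mp.band_intensity(hmap.spectrum_at(ix, iy)), rel=1e-12
            )

    def test_pnt2_hotspots_confined_to_planted_region(self, map_spec_factory):
        spec = map_spec_factory(3, noise_sd=0.0)
        hmap, mask, truth = syn.generate_cell_map("PNT2", 2, spec)
        img = mp.reconstruct_image(hmap)
        hot = img > 0.05 * img.max()
        assert hot.sum() > 0
        # every hot pixel coincides with planted load (signal is spot-confined)
        assert np.all(truth.load_field[hot] > 0)
        assert np.all(mask.grid[hot])

    def test_image_maximum_at_maximum_load(self, map_spec_factory):
        spec = map_spec_factory(6, noise_sd=0.0)
        hmap, _, truth = syn.generate_cell_map("PC3", 6, spec)
        img = mp.reconstruct_image(hmap)
        assert np.argmax(img) == np.argmax(truth.load_field)


class TestSumSpectrum:
    def test_single_pixel_mask(self):
        cube = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
        hmap = small_map(cube)
        grid = np.zeros((2, 3), dtype=bool)
        grid[1, 2] = True
        s = mp.sum_spectrum(hmap, CellMask(grid))
        np.testing.assert_allclose(s.intensity, cube[1, 2])

    def test_uniform_full_map(self):
        hmap = small_map(np.full((3, 5, 4), 2.5))
        s = mp.sum_spectrum(hmap, CellMask.full(3, 5))
        np.testing.assert_allclose(s.intensity, 15 * 2.5)

    def test_additivity_over_disjoint_masks(self, map_spec_factory):
        hmap, mask, _ = syn.generate_cell_map("PC3", 2, map_spec_factory(12))
        grid = mask.grid
        left = grid.copy()
        left[:, 15:] = False
        right = grid & ~left
        s_union = mp.sum_spectrum(hmap, CellMask(grid))
        s_parts = mp.sum_spectrum(hmap, CellMask(left)).intensity + mp.sum_spectrum(
            hmap, CellMask(right)
        ).intensity
        np.testing.assert_allclose(s_union.intensity, s_parts, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        hmap = small_map(np.ones((2, 3, 4)))
        with pytest.raises(MaskError):
            mp.sum_spectrum(hmap, CellMask(np.ones((3, 3), dtype=bool)))

    def test_empty_mask_rejected(self):
        hmap = small_map(np.ones((2, 3, 4)))
        with pytest.raises(MaskError):
            mp.sum_spectrum(hmap, CellMask(np.zeros((2, 3), dtype=bool)))


class TestComputeI1078:
    def test_blank_map_near_zero(self, map_spec_factory):
        spec = map_spec_factory(21, base_load=0.0)
        hmap, mask, _ = syn.generate_cell_map("PC3", 2, spec)
        result = mp.compute_i1078(hmap, mask)
        noise_floor = spec.noise_sd * np.sqrt(mask.n_pixels) / spec.exposure_s
        assert result.i1078 <= 3 * noise_floor

    @pytest.mark.parametrize("cell_line,time_h", [("PC3", 6), ("PNT2", 2)])
    def test_recovers_generator_truth(self, map_spec_factory, cell_line, time_h):
        hmap, mask, truth = syn.generate_cell_map(
            cell_line, time_h, map_spec_factory(31)
        )
        result = mp.compute_i1078(hmap, mask)
        assert result.i1078 == pytest.approx(truth.i1078, rel=0.05)

    def test_linearity_in_load(self, map_spec_factory):
        base = map_spec_factory(
            17, noise_sd=0.0, baseline=syn.BaselineParams((50.0, 10.0))
        )
        tripled = map_spec_factory(
            17, noise_sd=0.0, baseline=syn.BaselineParams((50.0, 10.0)),
            base_load=300.0,
        )
        h1, m1, _ = syn.generate_cell_map("PC3", 2, base)
        h3, m3, _ = syn.generate_cell_map("PC3", 2, tripled)
        i1 = mp.compute_i1078(h1, m1).i1078
        i3 = mp.compute_i1078(h3, m3).i1078
        assert i3 == pytest.approx(3 * i1, rel=1e-9)

    def test_mask_growth_over_blank_pixels_is_null(self, map_spec_factory):
        spec = map_spec_factory(22, noise_sd=0.0)
        hmap, mask, _ = syn.generate_cell_map("PC3", 2, spec)
        tight = mp.compute_i1078(hmap, mask).i1078
        full = mp.compute_i1078(hmap, CellMask.full(hmap.ny, hmap.nx)).i1078
        assert full == pytest.approx(tight, rel=0.01)


class TestSummarizeUptake:
    @staticmethod
    def results(line, time_h, values):
        return [
            UptakeResult(f"{line}-{i}", line, time_h, v) for i, v in enumerate(values)
        ]

    def test_260_percent_contrast(self):
        res = self.results("PC3", 2, [3.6, 3.6]) + self.results("PNT2", 2, [1.0, 1.0])
        summary = mp.summarize_uptake(res)
        assert summary.percent_excess[2] == pytest.approx(260.0)

    def test_950_percent_contrast(self):
        res = self.results("PC3", 6, [10.5]) + self.results("PNT2", 6, [1.0])
        assert mp.summarize_uptake(res).percent_excess[6] == pytest.approx(950.0)

    def test_identical_groups_zero_excess(self):
        res = self.results("PC3", 2, [2.0, 2.0]) + self.results("PNT2", 2, [2.0, 2.0])
        assert mp.summarize_uptake(res).percent_excess[2] == pytest.approx(0.0)

    def test_group_statistics(self):
        res = self.results("PNT2", 2, [1.0, 2.0, 3.0])
        g = mp.summarize_uptake(res, contrast=("PNT2", "PNT2")).groups[("PNT2", 2)]
        assert g.mean == pytest.approx(2.0)
        assert g.sd == pytest.approx(1.0)
        assert g.sem == pytest.approx(1.0 / np.sqrt(3))
        assert g.n_cells == 3

    def test_missing_reference_group_rejected(self):
        with pytest.raises(MissingReferenceGroupError):
            mp.summarize_uptake(self.results("PC3", 2, [1.0]))


@pytest.fixture(scope="module")
def pair():
    raman = syn.generate_tp_spectrum("raman", noise_sd=0.0)
    sers = syn.generate_tp_spectrum("sers", noise_sd=0.0)
    return raman, sers


class TestBandShiftTable:
    def test_cc_antisymmetric_shift(self, pair, band_table):
        rows = mp.band_shift_table(*pair, band_table)
        row = [r for r in rows if r.sers_nominal == 1078][0]
        assert row.shift == pytest.approx(1078 - 1096, abs=0.5)

    def test_sh_band_absent_in_sers(self, pair, band_table):
        rows = mp.band_shift_table(*pair, band_table)
        row = [r for r in rows if r.raman_nominal == 920][0]
        assert row.sers_absent
        assert row.raman_detected == pytest.approx(920, abs=1.0)

    def test_identical_spectra_zero_shifts(self, band_table):
        raman = syn.generate_tp_spectrum("raman", noise_sd=0.0)
        rows = mp.band_shift_table(raman, raman, band_table)
        detected = [r for r in rows if r.shift is not None]
        assert detected, "expected at least the strong bands detected"
        assert all(abs(r.shift) < 0.5 for r in detected)


class TestAveragePointSpectra:
    def test_identical_replicates_zero_sd(self):
        s = syn.generate_tp_spectrum("sers", noise_sd=0.0)
        mean, sd = mp.average_point_spectra([s, s, s])
        np.testing.assert_allclose(sd.intensity, 0.0, atol=1e-9)
        np.testing.assert_allclose(mean.intensity, s.intensity)

    def test_two_point_mean_and_sd(self):
        axis = np.arange(1000.0, 1010.0, 2.0)
        a = Spectrum(axis, np.zeros_like(axis))
        b = Spectrum(axis, np.full_like(axis, 2.0))
        mean, sd = mp.average_point_spectra([a, b])
        np.testing.assert_allclose(mean.intensity, 1.0)
        np.testing.assert_allclose(sd.intensity, np.sqrt(2.0))

    def test_noise_sd_estimate_from_20_replicates(self):
        sigma = 5.0
        reps = [
            syn.generate_tp_spectrum("sers", noise_sd=sigma, seed=500 + i)
            for i in range(20)
        ]
        _, sd = mp.average_point_spectra(reps)
        assert abs(sd.intensity.mean() - sigma) / sigma < 0.25

    def test_mismatched_axes_rejected(self):
        a = Spectrum(np.arange(5.0), np.zeros(5))
        b = Spectrum(np.arange(1.0, 6.0), np.zeros(5))
        with pytest.raises(SpectralAxisError):
            mp.average_point_spectra([a, b])
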