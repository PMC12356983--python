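"""Spectral types, resampling, illuminants and bundled sensitivities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import melanoscene as ms
from melanoscene.errors import (
    ExtrapolationError,
    GridMismatchError,
    ReflectanceRangeError,
    SceneFormatError,
)
from melanoscene.spectra import (
    WORKING_GRID,
    color_matching_functions,
    daylight_locus_chromaticity,
)


class TestSpectralFunction:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(SceneFormatError):
            ms.SpectralFunction([400, 410, 420], [1.0, 2.0])

    def test_rejects_decreasing_grid(self):
        with pytest.raises(SceneFormatError):
            ms.SpectralFunction([420, 410, 400], [1.0, 2.0, 3.0])

    def test_rejects_out_of_range_grid(self):
        with pytest.raises(SceneFormatError):
            ms.SpectralFunction([300, 400], [1.0, 1.0])

    def test_rejects_negative_and_nonfinite_values(self):
        with pytest.raises(SceneFormatError):
            ms.SpectralFunction([400, 410], [1.0, -0.5])
        with pytest.raises(SceneFormatError):
            ms.SpectralFunction([400, 410], [1.0, np.nan])


class TestResampleSpectrum:
    def test_constant_is_preserved(self):
        f = ms.SpectralFunction(np.arange(400, 701, 10.0), np.full(31, 3.0))
        out = ms.resample_spectrum(f, np.arange(400, 701, 5.0))
        assert np.allclose(out.values, 3.0)

    def test_midpoint_linear_interpolation(self):
        f = ms.SpectralFunction(np.arange(400, 701, 10.0), np.arange(0, 310, 10.0))
        out = ms.resample_spectrum(f, np.array([400.0, 405.0]))
        assert out.values[1] == pytest.approx(5.0)

    def test_identity_on_source_grid(self):
        f = ms.SpectralFunction(np.arange(400, 701, 5.0), np.linspace(0, 1, 61))
        out = ms.resample_spectrum(f, f.wavelengths_nm)
        assert np.array_equal(out.values, f.values)

    def test_no_silent_extrapolation(self):
        f = ms.SpectralFunction(np.arange(450, 651, 10.0), np.ones(21))
        with pytest.raises(ExtrapolationError):
            ms.resample_spectrum(f, np.arange(400, 701, 5.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_on_own_grid(self, seed):
        rng = np.random.default_rng(seed)
        f = ms.SpectralFunction(np.arange(400, 701, 10.0), rng.uniform(0, 5, 31))
        once = ms.resample_spectrum(f, np.arange(405, 696, 5.0))
        twice = ms.resample_spectrum(once, once.wavelengths_nm)
        assert np.array_equal(once.values, twice.values)


class TestResampleScene:
    def test_constant_cube(self):
        wl = np.arange(400, 701, 10.0)
        scene = ms.HyperspectralScene(
            np.full((2, 2, wl.size), 4.0), wl, "radiance", "natural", 30.0, "c"
        )
        out = ms.resample_scene(scene)
        assert out.wavelengths_nm.size == 61
        assert np.allclose(out.cube, 4.0)
        assert (out.quantity, out.environment, out.pixels_per_degree) == (
            "radiance", "natural", 30.0,
        )

    def test_identity_is_bitwise(self, radiance_scene):
        out = ms.resample_scene(radiance_scene)
        assert np.array_equal(out.cube, radiance_scene.cube)

    def test_matches_per_pixel_resample(self, rng):
        wl = np.arange(400, 701, 10.0)
        spectrum = rng.uniform(0, 2, wl.size)
        scene = ms.HyperspectralScene(
            spectrum[None, None, :], wl, "radiance", "natural", 30.0, "one"
        )
        out = ms.resample_scene(scene)
        oracle = ms.resample_spectrum(
            ms.SpectralFunction(wl, spectrum), np.arange(400, 701, 5.0)
        )
        assert np.allclose(out.cube[0, 0], oracle.values)


class TestIlluminants:
    def test_daylight_chromaticity_on_locus(self):
        # the daylight model must reproduce its own locus chromaticity
        for cct in (4000.0, 6500.0, 25000.0):
            spd = ms.cie_daylight_spd(cct, grid=np.arange(380.0, 781.0, 5.0))
            x, y = ms.chromaticity(spd)
            xd, yd = daylight_locus_chromaticity(cct)
            assert abs(x - xd) < 1e-3 and abs(y - yd) < 1e-3

    def test_normalized_to_100_at_560(self):
        for cct in (4000.0, 9000.0, 25000.0):
            assert ms.cie_daylight_spd(cct)(560.0) == pytest.approx(100.0)

    def test_blue_shift_with_cct(self):
        cold = ms.cie_daylight_spd(25000.0)
        warm = ms.cie_daylight_spd(4000.0)
        assert cold(450.0) / cold(650.0) > warm(450.0) / warm(650.0)

    def test_cct_out_of_range(self):
        with pytest.raises(ValueError):
            ms.cie_daylight_spd(3000.0)
        with pytest.raises(ValueError):
            ms.cie_daylight_spd(30000.0)

    def test_equal_energy_is_constant(self):
        ees = ms.equal_energy_spd()
        assert np.ptp(ees.values) == 0.0
        assert ees.values[0] / ees.values[-1] == 1.0

    def test_equal_energy_chromaticity(self):
        # oracle: the equal-energy point of the bundled CMF tables themselves
        grid = np.arange(380.0, 781.0, 5.0)
        ees = ms.equal_energy_spd(grid=grid)
        cmf = color_matching_functions(grid)
        sums = cmf[:, 1:].sum(axis=0)
        expected = (sums[0] / sums.sum(), sums[1] / sums.sum())
        x, y = ms.chromaticity(ees)
        assert x == pytest.approx(expected[0], abs=1e-6)
        assert y == pytest.approx(expected[1], abs=1e-6)


class TestApplyIlluminant:
    def _flat_reflectance(self, value):
        cube = np.full((2, 2, WORKING_GRID.size), value)
        return ms.HyperspectralScene(
            cube, WORKING_GRID.copy(), "reflectance", "natural", 30.0, "flat"
        )

    def test_unit_reflectance_returns_illuminant(self):
        scene = self._flat_reflectance(1.0)
        ill = ms.cie_daylight_spd(6500.0)
        out = ms.apply_illuminant(scene, ill)
        assert out.quantity == "radiance"
        assert np.allclose(out.cube[1, 1], ill.values)

    def test_zero_reflectance_gives_zero(self):
        out = ms.apply_illuminant(self._flat_reflectance(0.0), ms.equal_energy_spd())
        assert np.all(out.cube == 0)

    def test_scalar_product(self):
        out = ms.apply_illuminant(
            self._flat_reflectance(0.5), ms.equal_energy_spd(value=2.0)
        )
        assert np.allclose(out.cube, 1.0)

    def test_linear_in_illuminant(self):
        scene = self._flat_reflectance(0.3)
        one = ms.apply_illuminant(scene, ms.equal_energy_spd(value=1.0))
        two = ms.apply_illuminant(scene, ms.equal_energy_spd(value=2.0))
        assert np.allclose(two.cube, 2.0 * one.cube)

    def test_grid_mismatch_rejected(self):
        scene = self._flat_reflectance(0.5)
        coarse = ms.SpectralFunction(np.arange(400, 701, 10.0), np.ones(31))
        with pytest.raises(GridMismatchError):
            ms.apply_illuminant(scene, coarse)

    def test_requires_reflectance(self, radiance_scene):
        with pytest.raises(SceneFormatError):
            ms.apply_illuminant(radiance_scene, ms.equal_energy_spd())


class TestSensitivities:
    # corneal peak bands: L/M near the stated 565/535 nm; S shifted to the
    # 440-nm corneal peak from its short-wave pigment; melanopsin shifted
    # long of its 480-nm pigment peak by the ocular media
    BANDS = {"L": (555, 575), "M": (525, 545), "S": (425, 455), "Mel": (481, 500)}

    @pytest.mark.parametrize("channel", ["L", "M", "S", "Mel", "Vlambda"])
    def test_nonnegative_peak_normalized(self, channel):
        s = ms.sensitivity(channel)
        assert np.all(s.values >= 0)
        assert s.values.max() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("channel,band", sorted(BANDS.items()))
    def test_peak_wavelengths(self, channel, band):
        s = ms.sensitivity(channel)
        peak = s.wavelengths_nm[np.argmax(s.values)]
        assert band[0] <= peak <= band[1]

    def test_melanopic_peak_shifted_from_pigment(self):
        s = ms.sensitivity("Mel")
        assert s.wavelengths_nm[np.argmax(s.values)] > 480.0


class TestSceneValidation:
    def test_reflectance_above_one_rejected(self):
        cube = np.full((2, 2, WORKING_GRID.size), 0.5)
        cube[0, 0, 3] = 1.2
        with pytest.raises(ReflectanceRangeError, match="1 value"):
            ms.HyperspectralScene(
                cube, WORKING_GRID.copy(), "reflectance", "natural", 30.0, "bad"
            )

    def test_nan_pixels_counted(self):
        cube = np.ones((2, 2, WORKING_GRID.size))
        cube[0, 0, 0] = np.nan
        cube[1, 1, 5] = np.nan
        with pytest.raises(SceneFormatError, match="2 non-finite"):
            ms.HyperspectralScene(
                cube, WORKING_GRID.copy(), "radiance", "natural", 30.0, "bad"
            )
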