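"""Scene generator determinism/statistics and silent-substitution stimuli."""

import numpy as np
import pytest

import melanoscene as ms
from melanoscene.errors import InfeasibleSpecError, RankDeficientError
from melanoscene.excitation import CHANNELS
from melanoscene.receptive_field import ReceptiveFieldSpec
from melanoscene.spectra import WORKING_GRID
from melanoscene.synthetic import (
    SILENCED_CHANNELS,
    SceneGeneratorSpec,
    SilentSubstitutionSpec,
    _response_matrix,
    gaussian_primaries,
    solve_silent_substitution,
)


class TestGenerateScene:
    def test_zero_sd_is_uniform(self):
        scene = ms.generate_scene(
            SceneGeneratorSpec(height=16, width=16, reflectance_sd=0.0, seed=3)
        )
        assert np.ptp(scene.cube) == 0.0
        assert scene.cube.flat[0] == pytest.approx(0.2)

    def test_seed_determinism(self):
        spec = SceneGeneratorSpec(height=32, width=32, seed=11)
        a = ms.generate_scene(spec)
        b = ms.generate_scene(spec)
        c = ms.generate_scene(SceneGeneratorSpec(height=32, width=32, seed=12))
        assert np.array_equal(a.cube, b.cube)
        assert not np.array_equal(a.cube, c.cube)

    @pytest.mark.parametrize("environment", ["natural", "human_made"])
    @pytest.mark.parametrize("correlation", ["white", "one_over_f"])
    def test_mean_near_target_and_valid_reflectance(self, environment, correlation):
        scene = ms.generate_scene(
            SceneGeneratorSpec(
                environment=environment,
                height=64,
                width=64,
                spatial_correlation=correlation,
                seed=5,
            )
        )
        target = {"natural": 0.2, "human_made": 0.5}[environment]
        assert abs(scene.cube.mean() - target) <= 0.1 * target
        assert scene.cube.min() >= 0.001 and scene.cube.max() <= 1.0
        assert scene.quantity == "reflectance"

    def test_infeasible_spec_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            ms.generate_scene(
                SceneGeneratorSpec(
                    height=32, width=32, mean_reflectance=0.95,
                    reflectance_sd=0.6, seed=0,
                )
            )

    def test_environment_gap_propagates_to_melanopsin(self):
        # 20 vs 20 scenes at the default reflectance gap: the human-made
        # melanopsin median must exceed the natural one decisively
        from melanoscene.contrast import between_patch_contrast

        medians = {"natural": [], "human_made": []}
        for env in medians:
            for k in range(20):
                scene = ms.generate_scene(
                    SceneGeneratorSpec(environment=env, height=96, width=96, seed=k)
                )
                rad = ms.apply_illuminant(scene, ms.equal_energy_spd())
                mel = ms.compute_all_channels(rad)["Mel"]
                layout = ms.tile_patches(
                    rad.shape, ReceptiveFieldSpec(1.37), rad.pixels_per_degree
                )
                cs = between_patch_contrast(ms.local_excitation(mel, layout))
                medians[env].append(np.median(cs.local_values))
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(medians["human_made"], medians["natural"], alternative="greater")
        assert stat.pvalue < 1e-3


class TestSolveSilentSubstitution:
    def test_zero_contrast_identical_spectra(self):
        bg, mod = solve_silent_substitution(
            SilentSubstitutionSpec(target_channel="Mel", target_contrast=0.0)
        )
        assert np.allclose(bg.values, mod.values, atol=1e-12)

    @pytest.mark.parametrize("target,contrast", [
        ("Mel", 0.3), ("Lum", 0.3), ("S", 0.3), ("L", 0.2), ("M", 0.2),
    ])
    def test_isolation_verified_by_integration(self, target, contrast):
        # oracle: integrate the solved spectra directly against the
        # sensitivity tables, independently of the solver's matrices
        bg, mod = solve_silent_substitution(
            SilentSubstitutionSpec(target_channel=target, target_contrast=contrast)
        )
        for ch in ("L", "M", "S", "Mel", "Lum"):
            sens = ms.sensitivity("Vlambda" if ch == "Lum" else ch)
            e_bg = 5.0 * float(np.dot(bg.values, sens.values))
            e_mod = 5.0 * float(np.dot(mod.values, sens.values))
            michelson = (e_mod - e_bg) / (e_mod + e_bg)
            if ch == target:
                assert michelson == pytest.approx(contrast, abs=1e-9)
            elif ch in SILENCED_CHANNELS[target]:
                assert abs(e_mod - e_bg) / e_bg < 1e-8

    def test_matches_independent_linear_solve(self):
        # five primaries make the melanopsin system square; cross-check the
        # solver against a hand-built solve of the same constraints
        prim = gaussian_primaries((430.0, 470.0, 510.0, 550.0, 620.0), 25.0)
        contrast = 0.02
        bg, mod = solve_silent_substitution(
            SilentSubstitutionSpec(
                target_channel="Mel", target_contrast=contrast, primaries=prim
            )
        )
        R = _response_matrix(prim)  # rows L, M, S, Mel, Lum
        w = np.ones(5)
        e_mel = R[3] @ w
        A = np.vstack([R[[0, 1, 2, 4]], R[3]])
        b = np.array([0, 0, 0, 0, 2 * contrast * e_mel])
        dw = np.linalg.solve(A, b)
        P = np.column_stack([p.values for p in prim])
        assert np.allclose(mod.values - bg.values, P @ dw, atol=1e-9)

    def test_rank_deficient_primaries_rejected(self):
        p = gaussian_primaries((500.0, 500.0, 500.0, 500.0), 20.0)
        with pytest.raises(RankDeficientError):
            solve_silent_substitution(
                SilentSubstitutionSpec(target_channel="Mel", primaries=p)
            )

    def test_out_of_gamut_contrast_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            solve_silent_substitution(
                SilentSubstitutionSpec(target_channel="Mel", target_contrast=0.9)
            )


class TestRenderValidationScene:
    def test_two_region_geometry(self):
        scene = ms.render_validation_scene(
            SilentSubstitutionSpec(target_channel="Mel", target_contrast=0.2)
        )
        h, w = scene.shape
        assert w == 2 * h
        left = scene.cube[:, : w // 2, :]
        right = scene.cube[:, w // 2 :, :]
        assert np.ptp(left.reshape(-1, 61), axis=0).max() == 0
        assert np.ptp(right.reshape(-1, 61), axis=0).max() == 0

    def test_zero_contrast_uniform_channels(self):
        from melanoscene.contrast import between_patch_contrast

        scene = ms.render_validation_scene(
            SilentSubstitutionSpec(target_channel="Mel", target_contrast=0.0)
        )
        maps = ms.compute_all_channels(scene)
        layout = ms.tile_patches(
            scene.shape, ReceptiveFieldSpec(1.37), scene.pixels_per_degree
        )
        for ch in ("L", "M", "S", "Mel", "Lum"):
            cs = between_patch_contrast(ms.local_excitation(maps[ch], layout))
            assert cs.contrasts.max() < 1e-12

    def test_checkerboard_layout(self):
        scene = ms.render_validation_scene(
            SilentSubstitutionSpec(
                target_channel="Mel", target_contrast=0.2, layout="checkerboard"
            )
        )
        from melanoscene.contrast import between_patch_contrast

        maps = ms.compute_all_channels(scene)
        layout = ms.tile_patches(
            scene.shape, ReceptiveFieldSpec(1.37), scene.pixels_per_degree
        )
        cs = between_patch_contrast(ms.local_excitation(maps["Mel"], layout))
        assert cs.contrasts.max() == pytest.approx(0.2, abs=1e-9)


class TestIsolationContract:
    @pytest.mark.parametrize("target", ["L", "M", "S", "Mel", "Lum"])
    def test_full_pipeline_isolation(self, target):
        # the complete readout path: render -> excitation maps -> windows ->
        # between-patch contrasts; non-target silenced channels stay at zero
        from melanoscene.contrast import between_patch_contrast

        contrast = 0.15
        scene = ms.render_validation_scene(
            SilentSubstitutionSpec(target_channel=target, target_contrast=contrast)
        )
        maps = ms.compute_all_channels(scene)
        layout = ms.tile_patches(
            scene.shape, ReceptiveFieldSpec(1.37), scene.pixels_per_degree
        )
        for ch in ("L", "M", "S", "Mel", "Lum"):
            cs = between_patch_contrast(ms.local_excitation(maps[ch], layout))
            if ch == target:
                assert cs.contrasts.max() == pytest.approx(contrast, abs=1e-6)
            elif ch in SILENCED_CHANNELS[target]:
                assert cs.contrasts.max() <= 1e-6
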