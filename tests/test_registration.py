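import numpy as np
import pytest
import SimpleITK as sitk
from scipy import ndimage

from msiroi.cubes import MSICube
from msiroi.errors import (QCError, RegistrationError, SelectionError,
                           ValidationError)
from msiroi.registration import (RegistrationParams, ScoreMap,
                                 SpatialTransform, nmf_scoremaps,
                                 register_maps, registration_qc, select_pair,
                                 warp_cube)


def _blob_map(shape=(40, 40), center=(20, 20), r=8):
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    return ndimage.gaussian_filter(
        (np.hypot(rr - center[0], cc - center[1]) < r).astype(float), 2.0)


class TestNmfScoremaps:
    def test_requested_rank_returned_and_deterministic(self, phantom_default):
        maps = nmf_scoremaps(phantom_default.msi, rank=8, seed=0)
        maps2 = nmf_scoremaps(phantom_default.msi, rank=8, seed=0)
        assert len(maps) == 8
        assert [m.component for m in maps] == list(range(1, 9))
        for a, b in zip(maps, maps2):
            np.testing.assert_array_equal(a.values, b.values)
        assert all(m.values.min() >= 0 for m in maps)
        # background pixels carry zero scores
        bg = ~phantom_default.msi.foreground_mask
        assert all(np.allclose(m.values[bg], 0) for m in maps)

    def test_rank_one_cube_reconstructed(self):
        spatial = _blob_map() + 0.01
        spectrum = np.abs(np.sin(np.arange(12))) + 0.1
        cube = MSICube((40, 40), 100.0, np.arange(12) + 100.0,
                       spatial[:, :, None] * spectrum,
                       np.ones((40, 40), dtype=bool))
        from sklearn.decomposition import NMF
        maps = nmf_scoremaps(cube, rank=2, seed=0)
        model = NMF(n_components=2, init="nndsvda", random_state=0,
                    max_iter=500)
        W = model.fit_transform(cube.spectra(foreground_only=False))
        recon = W @ model.components_
        X = cube.spectra(foreground_only=False)
        assert np.linalg.norm(recon - X) / np.linalg.norm(X) < 1e-3

    def test_rank_exceeding_dimensions_rejected(self, tiny_msi_cube):
        with pytest.raises(ValidationError, match="rank"):
            nmf_scoremaps(tiny_msi_cube, rank=50)


class TestSelectPair:
    def test_manual_mode_returns_requested_components(self):
        rng = np.random.default_rng(0)
        msi = [ScoreMap(rng.random((20, 20)), i, "msi") for i in range(1, 7)]
        hf = [ScoreMap(rng.random((20, 20)), i, "hf") for i in range(1, 7)]
        fixed, moving = select_pair(msi, hf, "manual", manual_choice=(5, 2))
        assert fixed.component == 5 and fixed.modality == "hf"
        assert moving.component == 2 and moving.modality == "msi"

    def test_auto_finds_shared_structure(self):
        rng = np.random.default_rng(1)
        shared = _blob_map()
        msi = [ScoreMap(rng.random((40, 40)), 1, "msi"),
               ScoreMap(shared + 0.02 * rng.random((40, 40)), 2, "msi")]
        hf = [ScoreMap(shared + 0.02 * rng.random((40, 40)), 1, "hf"),
              ScoreMap(rng.random((40, 40)), 2, "hf")]
        fixed, moving = select_pair(msi, hf, "auto")
        assert (fixed.component, moving.component) == (1, 2)

    def test_all_noise_raises_selection_error(self):
        rng = np.random.default_rng(2)
        msi = [ScoreMap(rng.random((40, 40)), i, "msi") for i in (1, 2)]
        hf = [ScoreMap(rng.random((40, 40)), i, "hf") for i in (1, 2)]
        with pytest.raises(SelectionError, match="manual"):
            select_pair(msi, hf, "auto")


class TestRegisterMaps:
    def test_self_registration_is_identity(self):
        m = _blob_map()
        tr = register_maps(ScoreMap(m, 1, "hf"), ScoreMap(m.copy(), 1, "msi"))
        assert tr.mean_displacement() < 0.1

    def test_known_translation_recovered(self):
        fixed = _blob_map(center=(20, 20))
        moving = _blob_map(center=(23, 22))   # moving content shifted +3,+2
        tr = register_maps(ScoreMap(fixed, 1, "hf"),
                           ScoreMap(moving, 1, "msi"))
        disp = tr.displacement_field()
        tissue = fixed > 0.2
        # T maps fixed points onto the moving blob: displacement ~ (+3,+2)
        assert abs(disp[tissue, 0].mean() - 3.0) <= 1.0
        assert abs(disp[tissue, 1].mean() - 2.0) <= 1.0

    def test_blank_moving_map_rejected(self):
        with pytest.raises(RegistrationError, match="constant"):
            register_maps(ScoreMap(_blob_map(), 1, "hf"),
                          ScoreMap(np.zeros((40, 40)), 1, "msi"))


class TestWarpCube:
    def _identity_transform(self, shape):
        return SpatialTransform(sitk.Transform(2, sitk.sitkIdentity),
                                shape, shape)

    def test_identity_transform_preserves_cube(self, phantom_default):
        cube = phantom_default.msi
        out = warp_cube(cube, self._identity_transform(cube.grid_shape),
                        cube.grid_shape)
        np.testing.assert_allclose(out.intensities, cube.intensities,
                                   atol=1e-9)
        np.testing.assert_array_equal(out.foreground_mask,
                                      cube.foreground_mask)

    def test_integer_translation_matches_array_shift(self, phantom_default):
        cube = phantom_default.msi
        t = sitk.TranslationTransform(2)
        t.SetOffset((2.0, 0.0))   # sample moving at x+2
        tr = SpatialTransform(t, cube.grid_shape, cube.grid_shape)
        out = warp_cube(cube, tr, cube.grid_shape)
        expected = np.zeros_like(cube.intensities)
        expected[:, :-2] = cube.intensities[:, 2:]
        np.testing.assert_allclose(out.intensities, expected, atol=1e-9)

    def test_channel_axis_untouched(self, phantom_default):
        cube = phantom_default.msi
        out = warp_cube(cube, self._identity_transform(cube.grid_shape),
                        cube.grid_shape)
        assert out.n_channels == cube.n_channels
        np.testing.assert_array_equal(out.mz_axis, cube.mz_axis)

    def test_grid_mismatch_rejected(self, phantom_default):
        cube = phantom_default.msi
        with pytest.raises(ValidationError, match="moving domain"):
            warp_cube(cube, self._identity_transform((10, 10)), (10, 10))


class TestRegistrationQc:
    def test_identical_masks_dice_one(self):
        m = _blob_map() > 0.2
        qc = registration_qc(m, m)
        assert qc["dice"] == 1.0 and qc["jaccard"] == 1.0

    def test_disjoint_masks_dice_zero(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:3], b[7:] = True, True
        assert registration_qc(a, b)["dice"] == 0.0

    def test_empty_mask_rejected(self):
        m = _blob_map() > 0.2
        with pytest.raises(QCError):
            registration_qc(m, np.zeros_like(m))

    def test_dice_improves_after_registration(self, phantom_warped):
        ph = phantom_warped
        fixed = ScoreMap(ndimage.gaussian_filter(
            ph.hf.foreground_mask.astype(float), 1.5), 1, "hf")
        moving = ScoreMap(ndimage.gaussian_filter(
            ph.msi.foreground_mask.astype(float), 1.5), 1, "msi")
        tr = register_maps(fixed, moving)
        warped = warp_cube(ph.msi, tr, ph.hf.grid_shape)
        before = registration_qc(ph.hf.foreground_mask,
                                 ph.msi.foreground_mask)["dice"]
        after = registration_qc(ph.hf.foreground_mask,
                                warped.foreground_mask)["dice"]
        assert after > before
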