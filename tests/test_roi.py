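import numpy as np
import pytest

from msiroi.errors import ValidationError
from msiroi.phantom import PhantomParams, generate_phantom, inject_marker_ions
from msiroi.roi import (ROISet, extract_rois, integrate_labels, rank_ions,
                        render_label_rgb, render_overlay)
from msiroi.segmentation import Labeling


def _labeling(lmap, K=None, modality="msi"):
    mask = lmap > 0
    return Labeling(lmap[mask], K or int(lmap.max()), modality, 0, mask)


def _square_map(K=2):
    lmap = np.zeros((8, 8), dtype=int)
    lmap[1:7, 1:4] = 1
    lmap[1:7, 4:7] = 2
    return lmap


class TestIntegrateLabels:
    def test_identical_labelings_all_confident(self):
        lmap = _square_map()
        roiset = integrate_labels(_labeling(lmap), _labeling(lmap, modality="hf"),
                                  (1, 2))
        assert not roiset.unconfident_mask.any()
        assert roiset.confident_mask.sum() == (lmap > 0).sum()

    def test_enumerated_disagreements_flagged(self):
        lmap = _square_map()
        other = lmap.copy()
        flipped = [(1, 1), (3, 5), (6, 2)]
        for r, c in flipped:
            other[r, c] = 3 - other[r, c]
        roiset = integrate_labels(_labeling(lmap),
                                  _labeling(other, modality="hf"), (1, 2))
        expected = np.zeros_like(lmap, dtype=bool)
        for r, c in flipped:
            expected[r, c] = True
        np.testing.assert_array_equal(roiset.unconfident_mask, expected)

    def test_permutation_must_be_bijection(self):
        lmap = _square_map()
        with pytest.raises(ValidationError, match="bijection"):
            integrate_labels(_labeling(lmap), _labeling(lmap, modality="hf"),
                             (1, 1))

    def test_partition_property_random_labelings(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            K = int(rng.integers(2, 6))
            lmap_a = np.zeros((12, 12), dtype=int)
            lmap_b = np.zeros((12, 12), dtype=int)
            fg = rng.random((12, 12)) < 0.7
            lmap_a[fg] = rng.integers(1, K + 1, int(fg.sum()))
            fg_b = rng.random((12, 12)) < 0.7
            lmap_b[fg_b] = rng.integers(1, K + 1, int(fg_b.sum()))
            if not lmap_a.max() or not lmap_b.max():
                continue
            perm = tuple(rng.permutation(K) + 1)
            roiset = integrate_labels(_labeling(lmap_a, K),
                                      _labeling(lmap_b, K, "hf"), perm)
            roiset.validate()
            shared = fg & fg_b
            cover = roiset.confident_mask | roiset.unconfident_mask
            np.testing.assert_array_equal(cover, shared)

    def test_salt_and_pepper_pixels_flagged(self):
        """Scattered mislabeled MSI pixels must surface as unconfident."""
        ph = generate_phantom(PhantomParams(
            msi_noise=0.0, hf_noise=0.0, tic_cv=0.0, deformation_px=0.0,
            saltpepper_rate=0.02), seed=1)
        # observed MSI labeling = ground truth corrupted at the planted
        # pixels; HF labeling = clean truth
        msi_map = ph.truth.labels_msi.copy()
        from msiroi.segmentation import spectral_segment
        from msiroi.validation import align_labels
        lab_msi = spectral_segment(ph.msi, K=4, seed=0)
        lab_hf = _labeling(ph.truth.labels_hf, 4, "hf")
        perm, _ = align_labels(lab_msi, lab_hf)
        roiset = integrate_labels(lab_msi, lab_hf, perm)
        planted = ph.truth.saltpepper_pixels
        flagged = roiset.unconfident_mask[planted[:, 0], planted[:, 1]]
        assert flagged.mean() >= 0.95


class TestExtractRois:
    def test_summary_counts(self):
        lmap = _square_map()
        roiset = integrate_labels(_labeling(lmap),
                                  _labeling(lmap, modality="hf"), (1, 2))
        regions = extract_rois(roiset)
        assert set(regions) == {1, 2}
        assert regions[1]["n_pixels"] == 18
        assert regions[1]["confident_fraction"] == pytest.approx(0.5)

    def test_fully_inconsistent_cluster_kept_empty_with_warning(self):
        lmap = _square_map()
        other = lmap.copy()
        other[lmap == 2] = 1
        other[lmap == 1] = 2
        roiset = integrate_labels(_labeling(lmap),
                                  _labeling(other, modality="hf"), (1, 2))
        with pytest.warns(UserWarning, match="no confident pixel"):
            regions = extract_rois(roiset)
        assert regions[1]["n_pixels"] == 0

    def test_phantom_regions_match_truth(self, phantom_clean):
        ph = phantom_clean
        lab = _labeling(ph.truth.labels_msi)
        roiset = integrate_labels(lab, _labeling(ph.truth.labels_hf, 4, "hf"),
                                  (1, 2, 3, 4))
        for rid, info in extract_rois(roiset).items():
            truth_mask = ph.truth.labels_hf == rid
            inter = (info["mask"] & truth_mask).sum()
            dice = 2 * inter / (info["mask"].sum() + truth_mask.sum())
            assert dice >= 0.9


class TestRankIons:
    def _roiset(self, ph):
        lab = _labeling(ph.truth.labels_msi)
        return integrate_labels(lab, _labeling(ph.truth.labels_hf, 4, "hf"),
                                (1, 2, 3, 4))

    def test_noise_free_marker_correlates_perfectly(self, phantom_clean):
        ph = phantom_clean
        cube = inject_marker_ions(ph.msi, ph.truth, noise_sigma=0.0)
        ranking = rank_ions(cube, self._roiset(ph), top_n=cube.n_channels)
        for region, ch in ph.truth.marker_channels.items():
            rs = dict(ranking.rankings[region])
            assert rs[cube.mz_axis[ch]] == pytest.approx(1.0, abs=1e-12)
            assert ranking.top_ion(region)[1] == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_noisy_marker_still_top_ranked(self):
        # realistic noise on the signature channels; marker sigma 0.1
        ph = generate_phantom(PhantomParams(deformation_px=0.0,
                                            saltpepper_rate=0.0), seed=1)
        cube = inject_marker_ions(ph.msi, ph.truth, noise_sigma=0.1, seed=2)
        lab = _labeling(ph.truth.labels_msi)
        roiset = integrate_labels(lab,
                                  _labeling(ph.truth.labels_hf, 4, "hf"),
                                  (1, 2, 3, 4))
        ranking = rank_ions(cube, roiset)
        for region, ch in ph.truth.marker_channels.items():
            assert ranking.top_ion(region)[0] == cube.mz_axis[ch]

    def test_constant_channel_excluded(self, phantom_clean):
        ph = phantom_clean
        cube = ph.msi.copy()
        cube.intensities[:, :, 0] = 1.0
        ranking = rank_ions(cube, self._roiset(ph))
        assert cube.mz_axis[0] in ranking.excluded_mz
        for pairs in ranking.rankings.values():
            assert cube.mz_axis[0] not in [mz for mz, _ in pairs]

    def test_invariant_to_affine_channel_rescaling(self, phantom_clean):
        ph = phantom_clean
        cube = inject_marker_ions(ph.msi, ph.truth, noise_sigma=0.2, seed=3)
        scaled = cube.copy()
        scaled.intensities = scaled.intensities * 7.5 + 0.3
        r1 = rank_ions(cube, self._roiset(ph))
        r2 = rank_ions(scaled, self._roiset(ph))
        for region in r1.rankings:
            for (mz1, v1), (mz2, v2) in zip(r1.rankings[region],
                                            r2.rankings[region]):
                assert mz1 == mz2
                assert v1 == pytest.approx(v2, abs=1e-9)


class TestRendering:
    def test_label_rgb_shape_and_palette(self):
        lmap = _square_map()
        roiset = integrate_labels(_labeling(lmap),
                                  _labeling(lmap, modality="hf"), (1, 2))
        rgb = render_label_rgb(roiset)
        assert rgb.shape == (8, 8, 3) and rgb.dtype == np.uint8

    def test_overlay_factor_one_keeps_geometry(self, phantom_default):
        he = phantom_default.he_image
        rows, cols = he.shape[0], he.shape[1]
        layer = np.zeros((rows, cols, 3), dtype=np.uint8)
        out = render_overlay(layer, he, 1, alpha=0.5, is_label_map=True)
        assert out.shape == he.shape

    def test_overlay_upsamples_by_tile_size(self, phantom_default):
        ph = phantom_default
        factor = ph.hf.tile_size_px
        layer = (ph.truth.labels_hf % 5).astype(float)
        out = render_overlay(layer, ph.he_image, factor, alpha=0.4)
        assert out.shape[0] == ph.truth.labels_hf.shape[0] * factor

    def test_overlay_factor_mismatch_rejected(self, phantom_default):
        layer = np.zeros((10, 10), dtype=float)
        with pytest.raises(ValidationError, match="factor"):
            render_overlay(layer, phantom_default.he_image, 3)
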