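"""Cohen's kappa, permutation alignment, K selection, and the internal
baselines, checked against hand computations and independent oracles."""

from itertools import permutations

import numpy as np
import pytest

from msiroi.errors import ValidationError
from msiroi.segmentation import Labeling
from msiroi.validation import (align_labels, cks_curve_select, cohen_kappa,
                               dbi_criterion, pc_criterion)


def oracle_best_permutation(a, b, K):
    """Brute-force alignment oracle: evaluate kappa from its definition for
    every relabeling of b, independently of the implementation's vectorized
    contingency arithmetic."""
    best_perm, best_kappa = None, -np.inf
    for perm in permutations(range(1, K + 1)):
        relabeled = np.array([perm[v - 1] for v in b])
        p_o = np.mean(a == relabeled)
        p_e = sum(np.mean(a == k) * np.mean(relabeled == k)
                  for k in range(1, K + 1))
        kappa = 1.0 if p_e >= 1 else (p_o - p_e) / (1 - p_e)
        if kappa > best_kappa + 1e-15:
            best_perm, best_kappa = perm, kappa
    return best_perm, best_kappa


class TestKappaProperties:
    """Structural invariants of kappa, over arbitrary label vectors."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    labels = st.lists(st.integers(1, 4), min_size=5, max_size=60)

    @given(labels)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_self_kappa_is_one_or_degenerate(self, a):
        import warnings as w
        a = np.asarray(a)
        with w.catch_warnings():
            w.simplefilter("ignore")
            kappa, table = cohen_kappa(a, a)
        assert kappa == 1.0
        assert table.n == len(a)

    @given(labels, labels, st.permutations([1, 2, 3, 4]))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_aligned_kappa_invariant_to_relabeling(self, a, b, perm):
        import warnings as w
        n = min(len(a), len(b))
        # anchor all four classes so both labelings share K = 4
        a = np.asarray([1, 2, 3, 4] + a[:n])
        b = np.asarray([1, 2, 3, 4] + b[:n])
        with w.catch_warnings():
            w.simplefilter("ignore")
            _, k0 = align_labels(a, b)
            _, k1 = align_labels(a, np.asarray(perm)[b - 1])
        assert k0 == pytest.approx(k1, abs=1e-12)


class TestCohenKappa:
    def test_self_agreement_is_exactly_one(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 5, 100)
        kappa, table = cohen_kappa(a, a)
        assert kappa == 1.0
        assert np.all(table.counts == np.diag(np.diag(table.counts)))

    def test_hand_computed_four_pixel_example(self):
        # a=(1,1,2,2), b=(1,2,2,2): p_o=0.75, p_e=0.5, kappa=0.5
        kappa, table = cohen_kappa(np.array([1, 1, 2, 2]),
                                   np.array([1, 2, 2, 2]))
        assert table.p_o == 0.75
        assert table.p_e == 0.5
        assert kappa == 0.5

    def test_matches_sklearn_on_random_pairs(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(1, 5, 200)
            b = rng.integers(1, 5, 200)
            kappa, _ = cohen_kappa(a, b, K=4)
            assert kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_labelings_center_on_zero(self):
        rng = np.random.default_rng(2)
        kappas = [cohen_kappa(rng.integers(1, 5, 500),
                              rng.integers(1, 5, 500), K=4)[0]
                  for _ in range(200)]
        assert abs(np.mean(kappas)) < 0.02

    def test_constant_equal_labelings_warn_kappa_one(self):
        with pytest.warns(UserWarning, match="constant"):
            kappa, _ = cohen_kappa(np.ones(10, dtype=int),
                                   np.ones(10, dtype=int), K=2)
        assert kappa == 1.0

    def test_shared_domain_is_mask_intersection(self):
        mask_a = np.array([[True, True, True, False]])
        mask_b = np.array([[False, True, True, True]])
        a = Labeling(np.array([1, 1, 2]), 2, "msi", 0, mask_a)
        b = Labeling(np.array([1, 2, 1]), 2, "hf", 0, mask_b)
        kappa, table = cohen_kappa(a, b)
        assert table.n == 2          # only the two overlapping pixels


class TestAlignLabels:
    def test_swapped_labels_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 4, 60)
        swap = {1: 2, 2: 1, 3: 3}
        b = np.array([swap[v] for v in a])
        perm, kappa = align_labels(a, b)
        assert perm == (2, 1, 3)
        assert kappa == 1.0

    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_equals_bruteforce_oracle(self, K):
        rng = np.random.default_rng(K)
        for _ in range(25):
            a = rng.integers(1, K + 1, 40)
            b = rng.integers(1, K + 1, 40)
            perm, kappa = align_labels(a, b)
            operm, okappa = oracle_best_permutation(a, b, K)
            assert kappa == pytest.approx(okappa, abs=1e-12)

    def test_alignment_absorbs_any_relabeling(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 5, 80)
        b = rng.integers(1, 5, 80)
        _, kappa0 = align_labels(a, b)
        perm = rng.permutation(4) + 1
        b_rel = perm[b - 1]
        _, kappa1 = align_labels(a, b_rel)
        assert kappa0 == pytest.approx(kappa1, abs=1e-12)

    def test_unequal_k_rejected(self):
        with pytest.raises(ValidationError, match="different K"):
            align_labels(np.array([1, 2, 2]), np.array([1, 2, 3]))

    def test_large_k_falls_back_with_warning(self):
        rng = np.random.default_rng(6)
        a = rng.integers(1, 11, 400)
        swap = np.roll(np.arange(1, 11), 3)
        b = swap[a - 1]
        with pytest.warns(UserWarning, match="suboptimal"):
            perm, kappa = align_labels(a, b)
        assert kappa == 1.0


class TestCksCurve:
    def test_identical_sweeps_select_smallest_k(self, phantom_default):
        from msiroi.segmentation import sweep_k
        labelings = sweep_k(phantom_default.hf, range(2, 5), seed=0)
        curve = cks_curve_select(labelings, labelings)
        assert curve.kappas == [1.0, 1.0, 1.0]
        assert curve.best_k == 2          # tie -> parsimony

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValidationError):
            cks_curve_select([], [])

    def test_mismatched_k_ranges_rejected(self, phantom_default):
        from msiroi.segmentation import sweep_k
        l23 = sweep_k(phantom_default.hf, range(2, 4), seed=0)
        l24 = sweep_k(phantom_default.hf, range(2, 5), seed=0)
        with pytest.raises(ValidationError):
            cks_curve_select(l23, l24)


def _labeling_from_map(lmap):
    mask = lmap > 0
    return Labeling(lmap[mask], int(lmap.max()), "msi", 0, mask)


class TestPcCriterion:
    def test_true_geometry_beats_shuffled(self, phantom_clean):
        ph = phantom_clean
        rng = np.random.default_rng(0)
        true_lab = _labeling_from_map(ph.truth.labels_msi)
        shuffled_map = ph.truth.labels_msi.copy()
        vals = shuffled_map[true_lab.foreground_mask]
        shuffled_map[true_lab.foreground_mask] = rng.permutation(vals)
        shuf_lab = _labeling_from_map(shuffled_map)
        res = pc_criterion(ph.msi, [true_lab, shuf_lab], runs=5, seed=0,
                           embed_method="pca")
        assert res.values[0] > res.values[1]
        assert len(res.dispersion) == 2

    def test_five_runs_reported_with_dispersion(self, phantom_clean):
        lab = _labeling_from_map(phantom_clean.truth.labels_msi)
        res = pc_criterion(phantom_clean.msi, [lab], runs=5, seed=0,
                           embed_method="pca")
        assert res.name == "PC"
        assert res.dispersion[0] >= 0.0
        assert -1.0 <= res.values[0] <= 1.0


class TestDbiCriterion:
    def test_matches_hand_computed_four_points(self):
        # two clusters of two points each: centroids (0, 0.5) and (10, 0.5),
        # mean within-cluster distance 0.5 each, centroid distance 10
        # -> R12 = (0.5 + 0.5) / 10 = 0.1 and DBI = 0.1
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        mask = np.ones((1, 4), dtype=bool)
        lab = Labeling(np.array([1, 1, 2, 2]), 2, "msi", 0, mask)
        res = dbi_criterion(None, [lab], features=X)
        assert res.values[0] == pytest.approx(0.1, abs=1e-12)

    def test_far_blobs_score_better_than_near(self):
        rng = np.random.default_rng(0)
        mask = np.ones((1, 80), dtype=bool)
        lab = Labeling(np.repeat([1, 2], 40), 2, "msi", 0, mask)
        base = rng.normal(0, 1, (80, 3))
        far = base.copy()
        far[40:, 0] += 20.0
        near = base.copy()
        near[40:, 0] += 1.0
        dbi_far = dbi_criterion(None, [lab], features=far).values[0]
        dbi_near = dbi_criterion(None, [lab], features=near).values[0]
        assert dbi_far < dbi_near

    def test_argmin_reported(self, phantom_clean):
        from msiroi.segmentation import sweep_k
        labelings = sweep_k(phantom_clean.msi, range(2, 6), seed=0)
        res = dbi_criterion(phantom_clean.msi, labelings)
        assert res.best_k == res.ks[int(np.argmin(res.values))]
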