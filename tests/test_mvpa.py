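"""MVPA protocol: masking, normalization, LOSO, permutation null, cross-task."""

import numpy as np
import pytest
from sklearn.svm import SVC

from sexdecode import mvpa, synthdata
from sexdecode.types import FEMALE, MALE
from tests.conftest import make_cohort_maps


def _feature_matrix(X, labels, mask=None):
    if mask is None:
        prob = synthdata.generate_tissue_probability((X.shape[1], 1, 1))
        mask = mvpa.mask_from_probability(prob)
    maps = [row.reshape(mask.mask.shape) for row in X]
    return mvpa.build_features(maps, mask, labels)


class TestMask:
    def test_uniform_half_keeps_all(self):
        mask = mvpa.mask_from_probability(np.full((4, 4, 4), 0.5))
        assert mask.count == 64

    def test_threshold_is_strict(self):
        with pytest.raises(ValueError, match="empty"):
            mvpa.mask_from_probability(np.full((4, 4, 4), 0.25))

    def test_default_threshold(self):
        prob = np.full((3, 3, 3), 0.26)
        assert mvpa.mask_from_probability(prob).threshold == 0.25


class TestBuildFeatures:
    def test_rows_standardized(self, full_mask_8):
        rng = np.random.default_rng(0)
        maps = [rng.normal(5.0, 3.0, size=(8, 8, 8)) for _ in range(6)]
        f = mvpa.build_features(maps, full_mask_8, [MALE] * 3 + [FEMALE] * 3)
        assert np.allclose(f.X.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(f.X.var(axis=1), 1.0, atol=1e-10)

    def test_affine_invariance(self, full_mask_8):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 8, 8))
        f = mvpa.build_features(
            [base, 3.0 * base + 7.0], full_mask_8, [MALE, FEMALE]
        )
        assert np.allclose(f.X[0], f.X[1], atol=1e-10)

    def test_constant_map_rejected_with_subject_name(self, full_mask_8):
        maps = [np.zeros((8, 8, 8)), np.random.default_rng(2).normal(size=(8, 8, 8))]
        with pytest.raises(ValueError, match="sub-001"):
            mvpa.build_features(maps, full_mask_8, [MALE, FEMALE])

    def test_per_voxel_normalization_standardizes_columns(self, full_mask_8):
        rng = np.random.default_rng(21)
        maps = [rng.normal(size=(8, 8, 8)) for _ in range(6)]
        f = mvpa.build_features(
            maps, full_mask_8, [MALE] * 3 + [FEMALE] * 3,
            normalization="per_voxel",
        )
        assert np.allclose(f.X.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(f.X.std(axis=0), 1.0, atol=1e-10)

    def test_order_preserved(self, full_mask_8):
        rng = np.random.default_rng(3)
        maps = [rng.normal(size=(8, 8, 8)) for _ in range(4)]
        labels = [MALE, FEMALE, MALE, FEMALE]
        f = mvpa.build_features(maps, full_mask_8, labels, subject_ids=list("abcd"))
        assert f.subject_ids == ("a", "b", "c", "d")
        assert list(f.labels) == labels


class TestLosoClassify:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 0.05, size=(20, 100))
        X[:10, :20] += 1.0
        X[10:, :20] -= 1.0
        f = _feature_matrix(X, [MALE] * 10 + [FEMALE] * 10)
        assert mvpa.loso_classify(f).accuracy == 1.0

    def test_random_labels_hover_at_chance(self):
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(30):
            X = rng.normal(size=(20, 200))
            labels = np.array([MALE] * 10 + [FEMALE] * 10)
            rng.shuffle(labels)
            accs.append(mvpa.loso_classify(_feature_matrix(X, list(labels))).accuracy)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 4 * se + 0.02

    def test_matches_exhaustive_fold_enumeration(self):
        # brute-force oracle: enumerate the 4 folds by hand with sklearn
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 30))
        X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        labels = np.array([MALE, FEMALE, MALE, FEMALE], dtype=object)
        f = _feature_matrix(X, list(labels))
        result = mvpa.loso_classify(f)
        expected = []
        for i in range(4):
            tr = [j for j in range(4) if j != i]
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(X[tr], labels[tr].astype(str))
            dec = clf.decision_function(X[[i]]) - clf.intercept_
            expected.append(MALE if dec[0] > 0 else FEMALE)
        assert list(result.predictions) == expected

    def test_confusion_rows_are_proportions(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 50))
        f = _feature_matrix(X, [MALE] * 6 + [FEMALE] * 6)
        res = mvpa.loso_classify(f)
        assert np.allclose(res.confusion.sum(axis=1), 1.0)

    def test_single_class_fold_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 20))
        f = _feature_matrix(X, [MALE, MALE, FEMALE])
        with pytest.raises(ValueError, match="two subjects"):
            mvpa.loso_classify(f)


class TestPermutationTest:
    def test_p_value_counts_null_at_least_observed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 80))
        f = _feature_matrix(X, [MALE] * 6 + [FEMALE] * 6)
        obs, null, p = mvpa.permutation_test(f, n_perm=60, seed=3)
        assert p == pytest.approx((null.accuracies >= obs.accuracy).mean())
        assert null.n_perm == 60
        assert np.all((null.accuracies >= 0) & (null.accuracies <= 1))

    def test_null_mean_near_chance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(16, 100))
        f = _feature_matrix(X, [MALE] * 8 + [FEMALE] * 8)
        _, null, _ = mvpa.permutation_test(f, n_perm=200, seed=4)
        se = 0.5 / np.sqrt(16)  # binomial SE of one LOSO accuracy at n=16
        assert abs(null.accuracies.mean() - 0.5) < 3 * se

    def test_separable_observed_beats_null(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 0.05, size=(12, 60))
        y = [MALE] * 6 + [FEMALE] * 6
        X[:6, :10] += 1.0
        X[6:, :10] -= 1.0
        obs, null, p = mvpa.permutation_test(_feature_matrix(X, y), n_perm=99, seed=5)
        assert obs.accuracy == 1.0
        assert obs.accuracy > null.q95
        assert p < 0.05

    def test_tiny_n_perm_refuses_p(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(8, 40))
        f = _feature_matrix(X, [MALE] * 4 + [FEMALE] * 4)
        with pytest.warns(RuntimeWarning, match="too small"):
            _, _, p = mvpa.permutation_test(f, n_perm=5, seed=0)
        assert np.isnan(p)


class TestCrossClassify:
    def test_identical_matrices_reduce_to_loso(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(14, 70))
        f = _feature_matrix(X, [MALE] * 7 + [FEMALE] * 7)
        for kernel in ("linear", "rbf"):
            a = mvpa.cross_classify(f, f, kernel=kernel)
            b = mvpa.loso_classify(f, kernel=kernel)
            assert list(a.predictions) == list(b.predictions)
            assert a.accuracy == b.accuracy

    def test_shared_topography_generalizes(self, short_movie_design):
        hits = 0
        for seed in range(3):
            maps_a, labels = make_cohort_maps(short_movie_design, seed=700 + seed, n=12)
            maps_b, _ = make_cohort_maps(short_movie_design, seed=800 + seed, n=12)
            # same amplitude topography, independent noise: regenerate with
            # shared amplitude draws
            spec = synthdata.CohortSpec(
                n_male=12, n_female=12, grid_shape=(8, 8, 8), n_volumes=100,
                effect_regions=(
                    synthdata.EffectRegion(
                        "r", synthdata.region_block((2, 2, 2), (3, 3, 3)),
                        0.5, -0.5, 0.5, "sexual",
                    ),
                ),
                noise_sd=1.5, seed=700 + seed,
            )
            amps = synthdata.draw_amplitudes(spec)
            import dataclasses

            from sexdecode import glm as _glm
            cohort_a = synthdata.generate_cohort(spec, short_movie_design, amplitudes=amps)
            cohort_b = synthdata.generate_cohort(
                dataclasses.replace(spec, seed=900 + seed), short_movie_design,
                amplitudes=amps,
            )
            prob = synthdata.generate_tissue_probability((8, 8, 8))
            mask = mvpa.mask_from_probability(prob)
            fa = mvpa.build_features(
                [_glm.fit_glm(s, short_movie_design).volume("sexual") for s in cohort_a],
                mask, [s.sex for s in cohort_a],
            )
            fb = mvpa.build_features(
                [_glm.fit_glm(s, short_movie_design).volume("sexual") for s in cohort_b],
                mask, [s.sex for s in cohort_b],
            )
            obs, null, _ = mvpa.cross_permutation_test(fa, fb, n_perm=49, seed=seed)
            hits += obs.accuracy > null.q95
        assert hits >= 2

    def test_disjoint_topographies_stay_at_chance(self, full_mask_8):
        rng = np.random.default_rng(14)
        accs = []
        for _ in range(10):
            amp = np.where(np.arange(24) < 12, 0.5, -0.5) + rng.normal(0, 0.5, 24)
            Xa = rng.normal(0, 0.3, size=(24, 512))
            Xb = rng.normal(0, 0.3, size=(24, 512))
            Xa[:, 10:20] += amp[:, None]
            Xb[:, 300:310] += amp[:, None]  # different voxels carry the signal
            labels = [MALE] * 12 + [FEMALE] * 12
            fa = _feature_matrix(Xa, labels, full_mask_8)
            fb = _feature_matrix(Xb, labels, full_mask_8)
            accs.append(mvpa.cross_classify(fa, fb).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_mismatched_ids_rejected(self, full_mask_8):
        rng = np.random.default_rng(15)
        maps = [rng.normal(size=(8, 8, 8)) for _ in range(4)]
        labels = [MALE, MALE, FEMALE, FEMALE]
        fa = mvpa.build_features(maps, full_mask_8, labels, subject_ids=list("abcd"))
        fb = mvpa.build_features(maps, full_mask_8, labels, subject_ids=list("abce"))
        with pytest.raises(ValueError, match="matching subject ids"):
            mvpa.cross_classify(fa, fb)


class TestWeightMap:
    def test_top_weights_overlap_planted_region(self, full_mask_8):
        rng = np.random.default_rng(16)
        amp = np.where(np.arange(20) < 10, 0.5, -0.5) + rng.normal(0, 0.25, 20)
        X = rng.normal(0, 0.3, size=(20, 512))
        region = np.arange(27)
        X[:, region] += amp[:, None]
        f = _feature_matrix(X, [MALE] * 10 + [FEMALE] * 10, full_mask_8)
        wmap = mvpa.weight_map(f)
        w = np.abs(wmap.data[full_mask_8.mask])
        top = np.argsort(w)[-51:]  # top decile of 512
        overlap = len(set(top) & set(region))
        # hypergeometric chance overlap would be ~51*27/512 ~ 2.7
        assert overlap >= 10

    def test_label_flip_negates_weights(self, full_mask_8):
        rng = np.random.default_rng(17)
        maps = [rng.normal(size=(8, 8, 8)) for _ in range(8)]
        labels = [MALE] * 4 + [FEMALE] * 4
        flipped = [FEMALE] * 4 + [MALE] * 4
        w1 = mvpa.weight_map(mvpa.build_features(maps, full_mask_8, labels))
        w2 = mvpa.weight_map(mvpa.build_features(maps, full_mask_8, flipped))
        # antisymmetric up to the QP solver's convergence tolerance
        assert np.allclose(w1.data, -w2.data, atol=1e-5)

    def test_zero_outside_mask(self):
        rng = np.random.default_rng(18)
        prob = np.full((6, 6, 6), 0.1)
        prob[:3] = 0.9
        mask = mvpa.mask_from_probability(prob)
        maps = [rng.normal(size=(6, 6, 6)) for _ in range(6)]
        wmap = mvpa.weight_map(
            mvpa.build_features(maps, mask, [MALE] * 3 + [FEMALE] * 3)
        )
        assert np.all(wmap.data[~mask.mask] == 0)


class TestWeightContrastCorrelation:
    def test_proportional_volumes_give_unit_correlation(self, full_mask_8):
        rng = np.random.default_rng(19)
        maps = [rng.normal(size=(8, 8, 8)) for _ in range(8)]
        f = mvpa.build_features(maps, full_mask_8, [MALE] * 4 + [FEMALE] * 4)
        wmap = mvpa.weight_map(f)
        r = mvpa.weight_contrast_correlation(wmap, 2.5 * wmap.data)
        assert r == pytest.approx(1.0)

    def test_independent_volumes_near_zero(self, full_mask_8):
        rng = np.random.default_rng(20)
        rs = []
        for _ in range(20):
            maps = [rng.normal(size=(8, 8, 8)) for _ in range(8)]
            f = mvpa.build_features(maps, full_mask_8, [MALE] * 4 + [FEMALE] * 4)
            wmap = mvpa.weight_map(f)
            rs.append(
                mvpa.weight_contrast_correlation(wmap, rng.normal(size=(8, 8, 8)))
            )
        assert abs(np.mean(rs)) < 0.1

    def test_shared_topography_gives_positive_r(self, short_movie_design):
        from sexdecode import glm as _glm
        from sexdecode import groupstats

        maps, labels = make_cohort_maps(short_movie_design, seed=21, n=12)
        prob = synthdata.generate_tissue_probability((8, 8, 8))
        mask = mvpa.mask_from_probability(prob)
        f = mvpa.build_features(maps, mask, labels)
        wmap = mvpa.weight_map(f)
        males = [m for m, s in zip(maps, labels) if s == MALE]
        females = [m for m, s in zip(maps, labels) if s == FEMALE]
        tmap = groupstats.two_sample_tmap(males, females, mask.mask)
        assert mvpa.weight_contrast_correlation(wmap, tmap) > 0.3
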