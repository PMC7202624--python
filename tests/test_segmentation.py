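import itertools

import numpy as np
import pytest
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from alveoquant import phantom, segmentation as seg
from alveoquant.errors import ValidationError
from alveoquant.image_io import PCLEImage
from oracles import pair_count_auc


def make_training_set(X, y, names=None):
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return seg.TrainingSet(
        X=X, y=y, feature_names=list(names),
        provenance=[("t", (0, i)) for i in range(len(y))],
    )


class TestComputeFeatures:
    def test_constant_image(self):
        img = PCLEImage(np.full((64, 64), 17.0), spacing_um=1.0)
        stack = seg.compute_features(img)
        for j, name in enumerate(stack.feature_names):
            plane = stack.features[..., j]
            if name.startswith(("gauss", "median")):
                np.testing.assert_allclose(plane, 17.0, rtol=1e-6)
            else:
                np.testing.assert_allclose(plane, 0.0, atol=1e-4)

    def test_single_bright_pixel_gaussian_peak(self):
        px = np.zeros((65, 65))
        px[32, 32] = 100.0
        stack = seg.compute_features(PCLEImage(px, spacing_um=1.0))
        j = stack.feature_names.index("gauss_s2")
        plane = stack.features[..., j]
        assert np.unravel_index(plane.argmax(), plane.shape) == (32, 32)

    def test_gaussian_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 255, size=(48, 48))
        stack = seg.compute_features(PCLEImage(px, spacing_um=1.0))
        j = stack.feature_names.index("gauss_s1")
        # independent dense 2D convolution with a sampled, normalized kernel
        radius = 4  # scipy's default truncate=4 at sigma=1
        ax = np.arange(-radius, radius + 1, dtype=float)
        g = np.exp(-(ax**2) / 2.0)
        g /= g.sum()
        kernel = np.outer(g, g)
        padded = np.pad(px, radius, mode="symmetric")  # scipy's "reflect"
        expected = np.empty_like(px)
        for r in range(px.shape[0]):
            for c in range(px.shape[1]):
                expected[r, c] = np.sum(
                    padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1] * kernel
                )
        np.testing.assert_allclose(stack.features[..., j], expected, rtol=1e-6)

    def test_features_finite(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(0, 255, size=(64, 64))
        stack = seg.compute_features(PCLEImage(px, spacing_um=1.0))
        assert np.isfinite(stack.features).all()

    def test_name_count_matches_depth(self):
        bank = seg.FeatureBankConfig(scales=(1.0, 3.0))
        img = PCLEImage(np.zeros((64, 64)), spacing_um=1.0)
        stack = seg.compute_features(img, bank=bank)
        assert stack.features.shape[-1] == len(stack.feature_names) == 16


class TestCollectInstances:
    @pytest.fixture()
    def stack(self):
        rng = np.random.default_rng(2)
        img = PCLEImage(rng.uniform(0, 255, size=(64, 64)), spacing_um=1.0)
        return seg.compute_features(img, bank=seg.FeatureBankConfig(scales=(1.0,)))

    def test_counts(self, stack):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[10, :10] = 1
        labels[20, :10] = 2
        ts = seg.collect_instances(stack, labels)
        assert ts.n_instances == 20
        assert ts.class_counts() == {1: 10, 2: 10}

    def test_all_unlabelled_rejected(self, stack):
        with pytest.raises(ValidationError):
            seg.collect_instances(stack, np.zeros((64, 64), dtype=np.uint8))

    def test_single_class_rejected(self, stack):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels[5, 5] = 1
        with pytest.raises(ValidationError):
            seg.collect_instances(stack, labels)

    def test_count_equals_nonzero_labels_random(self, stack):
        rng = np.random.default_rng(3)
        labels = rng.choice([0, 0, 0, 1, 2], size=(64, 64)).astype(np.uint8)
        ts = seg.collect_instances(stack, labels)
        assert ts.n_instances == int((labels > 0).sum())


class TestUndersample:
    def _set(self, n_bg, n_el, seed=0):
        rng = np.random.default_rng(seed)
        n = n_bg + n_el
        y = np.array([2] * n_bg + [1] * n_el)
        return make_training_set(rng.normal(size=(n, 3)), y)

    def test_500_200_to_200_200(self):
        out = seg.undersample(self._set(500, 200), seed=0)
        assert out.class_counts() == {1: 200, 2: 200}

    def test_minority_untouched(self):
        ts = self._set(500, 200)
        out = seg.undersample(ts, seed=0)
        np.testing.assert_array_equal(out.X[out.y == 1], ts.X[ts.y == 1])

    def test_balanced_unchanged(self):
        ts = self._set(300, 300)
        out = seg.undersample(ts, seed=0)
        np.testing.assert_array_equal(out.X, ts.X)
        np.testing.assert_array_equal(out.y, ts.y)

    def test_reported_imbalance_ratio_to_one(self):
        # ~2.5x more background than elastin instances (typical labelling imbalance)
        out = seg.undersample(self._set(1000, 400), seed=1)
        counts = out.class_counts()
        assert counts[1] == counts[2] == 400

    def test_deterministic_by_seed(self):
        ts = self._set(100, 40)
        a = seg.undersample(ts, seed=5)
        b = seg.undersample(ts, seed=5)
        np.testing.assert_array_equal(a.X, b.X)

    def test_sampled_without_replacement(self):
        ts = self._set(100, 40)
        out = seg.undersample(ts, seed=2)
        bg = out.X[out.y == 2]
        assert np.unique(bg, axis=0).shape[0] == bg.shape[0]


class TestCFS:
    def _duplicated_feature_set(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(1, 3, size=n)
        informative = (y == 1).astype(float) + rng.normal(scale=0.3, size=n)
        noise = rng.normal(size=n)
        X = np.column_stack([informative, informative.copy(), noise])
        return make_training_set(X, y, names=["inf_a", "inf_b", "noise"])

    def test_duplicate_feature_collapsed(self):
        ts = self._duplicated_feature_set()
        selected = seg.select_features_cfs(ts)
        assert len([n for n in selected if n.startswith("inf")]) == 1

    def test_exhaustive_merit_agrees(self):
        ts = self._duplicated_feature_set()
        _, r_cf, r_ff = seg._su_tables(ts)
        merits = {
            subset: seg.cfs_merit(r_cf, r_ff, list(subset))
            for k in (1, 2, 3)
            for subset in itertools.combinations(range(3), k)
        }
        best = max(merits, key=merits.get)
        selected = seg.select_features_cfs(ts)
        idx = tuple(sorted(ts.feature_names.index(n) for n in selected))
        assert merits[idx] == pytest.approx(merits[best], rel=1e-9)

    def test_perfect_feature_selected_among_noise(self):
        rng = np.random.default_rng(4)
        n = 1000
        y = rng.integers(1, 3, size=n)
        X = np.column_stack(
            [rng.normal(size=n), (y == 1).astype(float), rng.normal(size=n)]
        )
        ts = make_training_set(X, y, names=["n1", "perfect", "n2"])
        assert "perfect" in seg.select_features_cfs(ts)

    def test_selected_merit_at_least_every_singleton(self):
        ts = self._duplicated_feature_set(seed=5)
        _, r_cf, r_ff = seg._su_tables(ts)
        selected = seg.select_features_cfs(ts)
        idx = [ts.feature_names.index(n) for n in selected]
        merit = seg.cfs_merit(r_cf, r_ff, idx)
        for j in range(3):
            assert merit >= seg.cfs_merit(r_cf, r_ff, [j]) - 1e-12

    def test_merit_invariant_to_feature_order(self):
        ts = self._duplicated_feature_set(seed=6)
        perm = [2, 0, 1]
        ts_perm = make_training_set(
            ts.X[:, perm], ts.y, names=[ts.feature_names[j] for j in perm]
        )
        _, r_cf, r_ff = seg._su_tables(ts)
        _, r_cf_p, r_ff_p = seg._su_tables(ts_perm)
        sel = seg.select_features_cfs(ts)
        sel_p = seg.select_features_cfs(ts_perm)
        m = seg.cfs_merit(r_cf, r_ff, [ts.feature_names.index(n) for n in sel])
        m_p = seg.cfs_merit(
            r_cf_p, r_ff_p, [ts_perm.feature_names.index(n) for n in sel_p]
        )
        assert m == pytest.approx(m_p, rel=1e-9)

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        n = 500
        y = rng.integers(1, 3, size=n)
        X = np.column_stack([(y == 1).astype(float), np.full(n, 3.0)])
        ts = make_training_set(X, y, names=["good", "const"])
        with pytest.warns(UserWarning, match="const"):
            selected = seg.select_features_cfs(ts)
        assert selected == ["good"]


class TestGainRatio:
    def test_perfect_predictor_ratio_one(self):
        rng = np.random.default_rng(8)
        y = rng.integers(1, 3, size=400)
        X = np.column_stack([(y == 1).astype(float), rng.normal(size=400)])
        ts = make_training_set(X, y, names=["perfect", "noise"])
        ranking = seg.rank_information_gain_ratio(ts)
        assert ranking[0][0] == "perfect"
        assert ranking[0][1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(9)
        n = 10_000
        y = rng.integers(1, 3, size=n)
        ts = make_training_set(rng.normal(size=(n, 1)), y, names=["indep"])
        ranking = dict(seg.rank_information_gain_ratio(ts))
        assert ranking["indep"] < 0.01

    def test_constant_feature_zero_by_convention(self):
        rng = np.random.default_rng(10)
        y = rng.integers(1, 3, size=100)
        X = np.column_stack([np.full(100, 2.0), (y == 1).astype(float)])
        ts = make_training_set(X, y, names=["const", "good"])
        ranking = dict(seg.rank_information_gain_ratio(ts))
        assert ranking["const"] == 0.0


class TestTrainForest:
    def _blobs(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.normal(loc=(-2, -2), scale=0.5, size=(n // 2, 2)),
                rng.normal(loc=(2, 2), scale=0.5, size=(n // 2, 2)),
            ]
        )
        y = np.array([1] * (n // 2) + [2] * (n // 2))
        return make_training_set(X, y)

    def test_separable_blobs_resubstitution(self):
        ts = self._blobs()
        model = seg.train_forest(ts, n_trees=50, seed=0)
        pred = model.forest.predict(ts.X)
        assert (pred == ts.y).mean() >= 0.99

    def test_same_seed_identical_predictions(self):
        ts = self._blobs()
        probe = np.random.default_rng(1).normal(size=(100, 2)).astype(np.float32)
        p1 = seg.train_forest(ts, n_trees=30, seed=7).forest.predict_proba(probe)
        p2 = seg.train_forest(ts, n_trees=30, seed=7).forest.predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_n_trees(self):
        with pytest.raises(ValidationError):
            seg.train_forest(self._blobs(), n_trees=0, seed=0)

    def test_more_trees_rarely_worse(self):
        # noisy overlapping classes: held-out AUC(200 trees) >= AUC(1 tree)
        # in at least 95 of 100 seeded repetitions
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            n = 240
            X = rng.normal(size=(n, 4))
            logits = X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=1.5, size=n)
            y = np.where(logits > 0, 1, 2)
            train, test = slice(0, 160), slice(160, n)
            ts = make_training_set(X[train], y[train])
            te = make_training_set(X[test], y[test])
            if len(np.unique(y[test])) < 2:
                wins += 1
                continue
            auc_many = seg.evaluate_roc(
                seg.train_forest(ts, n_trees=200, seed=rep), te
            )
            auc_one = seg.evaluate_roc(seg.train_forest(ts, n_trees=1, seed=rep), te)
            wins += auc_many >= auc_one
        assert wins >= 95


class TestPredictMask:
    def test_accuracy_on_phantom_family(self, phantom_model, small_bank):
        spec = phantom.PhantomSpec(
            image_size_px=128, n_seeds=16, snr=4.0, seed=777, width_um_sd=2.0
        )
        image, truth = phantom.generate_phantom(spec)
        stack = seg.compute_features(image, bank=small_bank)
        mask = seg.predict_mask(phantom_model, stack)
        acc = (mask.mask == truth.true_mask)[image.fov_mask].mean()
        assert acc >= 0.90

    def test_threshold_extremes(self, phantom_model, small_bank):
        import dataclasses

        spec = phantom.PhantomSpec(image_size_px=96, seed=88, snr=4.0)
        image, _ = phantom.generate_phantom(spec)
        stack = seg.compute_features(image, bank=small_bank)
        lo = dataclasses.replace(phantom_model, decision_threshold=0.0)
        hi = dataclasses.replace(phantom_model, decision_threshold=1.0)
        mask_lo = seg.predict_mask(lo, stack)
        assert (mask_lo.mask == image.fov_mask).all()
        mask_hi = seg.predict_mask(hi, stack)
        p = seg.predict_probability(phantom_model, stack)
        np.testing.assert_array_equal(mask_hi.mask, (p >= 1.0) & image.fov_mask)

    def test_outside_fov_forced_background(self, phantom_model, small_bank):
        spec = phantom.PhantomSpec(image_size_px=96, seed=89)
        image, _ = phantom.generate_phantom(spec)
        stack = seg.compute_features(image, bank=small_bank)
        mask = seg.predict_mask(phantom_model, stack)
        assert not mask.mask[~image.fov_mask].any()

    def test_feature_name_mismatch_rejected(self, phantom_model):
        spec = phantom.PhantomSpec(image_size_px=96, seed=90)
        image, _ = phantom.generate_phantom(spec)
        other = seg.compute_features(image, bank=seg.FeatureBankConfig(scales=(3.0,)))
        with pytest.raises(ValidationError, match="missing"):
            seg.predict_mask(phantom_model, other)


class TestEvaluateRoc:
    def _model_and_test(self):
        rng = np.random.default_rng(11)
        n = 300
        X = rng.normal(size=(n, 3))
        y = np.where(X[:, 0] + rng.normal(scale=0.8, size=n) > 0, 1, 2)
        model = seg.train_forest(make_training_set(X[:200], y[:200]), n_trees=40, seed=0)
        return model, make_training_set(X[200:], y[200:])

    def test_matches_pair_counting_oracle(self):
        model, test = self._model_and_test()
        auc = seg.evaluate_roc(model, test)
        p = model.forest.predict_proba(test.X)[:, list(model.forest.classes_).index(1)]
        assert auc == pytest.approx(pair_count_auc(p, test.y == 1), abs=1e-12)

    def test_perfectly_separated_scores(self):
        scores = np.concatenate([np.full(50, 0.9), np.full(50, 0.1)])
        labels = np.array([True] * 50 + [False] * 50)
        assert roc_auc_score(labels, scores) == 1.0
        assert pair_count_auc(scores, labels) == 1.0

    def test_permuted_labels_near_half(self):
        model, test = self._model_and_test()
        rng = np.random.default_rng(12)
        big = make_training_set(
            np.repeat(test.X, 20, axis=0), rng.permutation(np.repeat(test.y, 20))
        )
        auc = seg.evaluate_roc(model, big)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        scores = rng.uniform(size=200)
        labels = rng.uniform(size=200) < scores
        a = roc_auc_score(labels, scores)
        b = roc_auc_score(labels, np.exp(5 * scores) - 2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        model, test = self._model_and_test()
        bad = make_training_set(test.X, np.ones_like(test.y))
        with pytest.raises(ValidationError):
            seg.evaluate_roc(model, bad)


class TestModelSerialization:
    def test_roundtrip(self, tmp_path, phantom_model, small_bank):
        path = tmp_path / "model.joblib"
        phantom_model.save(path)
        loaded = seg.ClassifierModel.load(path)
        assert loaded.selected_features == phantom_model.selected_features
        assert loaded.bank == phantom_model.bank
        spec = phantom.PhantomSpec(image_size_px=96, seed=91)
        image, _ = phantom.generate_phantom(spec)
        stack = seg.compute_features(image, bank=small_bank)
        np.testing.assert_array_equal(
            seg.predict_mask(loaded, stack).mask,
            seg.predict_mask(phantom_model, stack).mask,
        )

    def test_incompatible_bank_version_refused(self, tmp_path, phantom_model):
        import joblib

        path = tmp_path / "model.joblib"
        phantom_model.save(path)
        blob = joblib.load(path)
        blob["bank_version"] = "0"
        joblib.dump(blob, path)
        with pytest.raises(ValidationError, match="version"):
            seg.ClassifierModel.load(path)
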