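"""GPR engine: kernel, fit/predict, hyperparameter search, dataset curation."""

import numpy as np
import pytest

from crystalgp import gpr
from crystalgp.gpr import (
    Hyperparameters,
    LabelledDataset,
    fit,
    freedman_diaconis_bins,
    kernel_rbf_cyclic,
    optimize_hyperparameters,
    predict,
    recovery_filter,
    s_curve,
    stratified_split,
    validation_rmse,
)


class TestKernel:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=6)
        assert kernel_rbf_cyclic(x, x, np.ones(6)) == 1.0

    def test_single_feature_closed_form(self):
        assert kernel_rbf_cyclic([0.0], [1.0], [1.0]) == pytest.approx(np.exp(-1.0))

    def test_cyclic_wrap_uses_short_arc(self):
        wrap = 2 * np.pi - 6.2
        expected = kernel_rbf_cyclic([0.0], [wrap], [1.0])
        assert kernel_rbf_cyclic([3.1], [-3.1], [1.0], [True]) == pytest.approx(expected, rel=1e-12)
        # without the cyclic flag the raw 6.2 distance applies
        assert kernel_rbf_cyclic([3.1], [-3.1], [1.0]) == pytest.approx(np.exp(-6.2**2))

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=4), rng.normal(size=4)
            th = rng.uniform(0.1, 3.0, 4)
            k = kernel_rbf_cyclic(x, y, th)
            assert k == pytest.approx(kernel_rbf_cyclic(y, x, th))
            assert 0.0 < k <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kernel_rbf_cyclic([1.0, 2.0], [1.0], [1.0, 1.0])


class TestFitPredict:
    def test_single_point_interpolates(self):
        ds = LabelledDataset([[0.5, 1.0]], [3.0])
        model = fit(ds, Hyperparameters([1.0, 1.0], 1e-14))
        assert predict(model, [0.5, 1.0]) == pytest.approx(3.0, abs=1e-10)

    def test_training_points_reproduced_at_small_noise(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(3), 1e-12))
        assert np.abs(predict(model, X) - y).max() < 1e-6

    def test_zero_weights_give_mean(self, rng):
        X = rng.normal(size=(4, 2))
        model = fit(LabelledDataset(X, np.full(4, 2.5)), Hyperparameters(np.ones(2)))
        # constant outputs -> y - mean = 0 -> alpha = 0 -> prediction = mean
        assert np.allclose(model.alpha, 0.0)
        assert predict(model, rng.normal(size=2)) == pytest.approx(2.5)

    def test_single_point_closed_form(self):
        model = fit(LabelledDataset([[0.0]], [2.0]), Hyperparameters([1.0], 1e-14))
        model.mean = 0.0
        model.alpha = np.array([2.0])
        assert predict(model, [1.0]) == pytest.approx(2.0 * np.exp(-1.0))

    def test_reversion_to_mean_far_away(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(2), 1e-10))
        far = np.full(2, 100.0)
        assert predict(model, far) == pytest.approx(model.mean, abs=1e-10)

    def test_mean_is_arithmetic_mean(self, rng):
        X = rng.normal(size=(7, 2))
        y = rng.normal(size=7)
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(2)))
        assert model.mean == pytest.approx(y.mean())

    def test_conflicting_duplicates_raise_unless_averaged(self):
        ds = LabelledDataset([[0.0], [0.0]], [1.0, 3.0])
        with pytest.raises(ValueError, match="duplicate"):
            fit(ds, Hyperparameters([1.0], 1e-14))
        model = fit(ds, Hyperparameters([1.0], 1e-14), allow_duplicates=True)
        assert predict(model, [0.0]) == pytest.approx(2.0, abs=1e-8)

    def test_kernel_periodicity_of_predictions(self, rng):
        X = rng.uniform(-np.pi, np.pi, size=(6, 3))
        y = rng.normal(size=6)
        cyclic = np.array([False, False, True])
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(3), 1e-10), cyclic=cyclic)
        x = rng.uniform(-np.pi, np.pi, size=3)
        shifted = x + np.array([0.0, 0.0, 2.0 * np.pi])
        assert predict(model, shifted) == pytest.approx(predict(model, x), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        cyclic = np.array([False, False, True])
        model = fit(LabelledDataset(X, y), Hyperparameters([0.7, 1.3, 0.5], 1e-10), cyclic=cyclic)
        x = rng.normal(size=3)
        g = gpr.predict_gradient(model, x)
        h = 1e-6
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[d] += h
            xm[d] -= h
            fd = (predict(model, xp) - predict(model, xm)) / (2 * h)
            assert g[d] == pytest.approx(fd, abs=1e-6)

    def test_gram_matrix_psd_property(self, rng):
        from crystalgp.gpr import _sq_dists

        for _ in range(100):
            X = rng.normal(size=(rng.integers(2, 12), rng.integers(1, 5)))
            th = rng.uniform(0.05, 5.0, X.shape[1])
            K = np.exp(-_sq_dists(X, X, th, None)) + 1e-10 * np.eye(len(X))
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() > -1e-12


class TestHyperparameterSearch:
    def test_rmse_objective_hand_value(self):
        # errors {3, 4} over two validation points
        ds = LabelledDataset([[0.0], [10.0]], [3.0, -4.0])
        model = fit(LabelledDataset([[100.0]], [0.0]), Hyperparameters([1.0]))
        # far from training -> predicts the mean 0 -> errors are |y|
        assert validation_rmse(model, ds) == pytest.approx(3.535534, abs=1e-6)

    def test_perfect_predictions_zero_objective(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(2), 1e-12))
        assert validation_rmse(model, LabelledDataset(X, y)) < 1e-6

    def test_optimized_beats_baselines_on_sine(self):
        X = np.linspace(0.0, 6.0, 60)[:, None]
        y = np.sin(X).ravel()
        train = LabelledDataset(X[::2], y[::2])
        val = LabelledDataset(X[1::2], y[1::2])
        hp = optimize_hyperparameters(train, val, bounds=(1e-3, 1e6), seed=7)
        opt = validation_rmse(fit(train, hp), val)
        unit = validation_rmse(fit(train, Hyperparameters([1.0])), val)
        delta = validation_rmse(fit(train, Hyperparameters([1e6])), val)
        assert opt <= unit
        assert opt < delta

    def test_empty_validation_rejected(self, rng):
        train = LabelledDataset(rng.normal(size=(4, 1)), rng.normal(size=4))
        with pytest.raises(ValueError):
            optimize_hyperparameters(train, train.take([]), seed=0)

    def test_noise_bounds_respected_when_optimized(self, rng):
        X = rng.normal(size=(20, 1))
        y = np.sin(X).ravel() + 0.01 * rng.normal(size=20)
        train = LabelledDataset(X[:12], y[:12])
        val = LabelledDataset(X[12:], y[12:])
        hp = optimize_hyperparameters(train, val, optimize_noise=True, seed=3)
        assert 1e-14 <= hp.noise <= 1e-6


class TestRecoveryFilter:
    def test_boundary_is_inclusive(self):
        ds = LabelledDataset(
            np.zeros((3, 1)), [0.0, 0.0, 0.0],
            e_wfn=[0.5, 1.0, 1.5], e_iqa_sum=[0.0, 0.0, 0.0],
        )
        kept = recovery_filter(ds, threshold=1.0)
        assert len(kept) == 2
        assert list(kept.geometry_ids) == [0, 1]

    def test_clean_data_untouched(self, rng):
        e = rng.normal(size=10)
        ds = LabelledDataset(rng.normal(size=(10, 2)), rng.normal(size=10),
                             e_wfn=e, e_iqa_sum=e)
        assert len(recovery_filter(ds, threshold=1.0)) == 10
        assert len(recovery_filter(ds, threshold=0.0)) == 10

    def test_zero_threshold_keeps_exact_only(self):
        ds = LabelledDataset(np.zeros((2, 1)), [0.0, 0.0],
                             e_wfn=[1.0, 1.0], e_iqa_sum=[1.0, 0.9])
        assert len(recovery_filter(ds, threshold=0.0)) == 1

    def test_missing_energies_identified(self):
        ds = LabelledDataset(np.zeros((2, 1)), [0.0, 0.0],
                             e_wfn=[1.0, np.nan], e_iqa_sum=[1.0, 1.0],
                             geometry_ids=[7, 9])
        with pytest.raises(ValueError, match="9"):
            recovery_filter(ds, threshold=1.0)


class TestStratifiedSplit:
    def test_full_draw_is_permutation(self, rng):
        ds = LabelledDataset(rng.normal(size=(30, 2)), rng.normal(size=30))
        (sub,) = stratified_split(ds, (30,), seed=0)
        assert sorted(sub.geometry_ids) == list(range(30))

    def test_fd_bin_count_uniform_outputs(self, rng):
        y = rng.uniform(0.0, 1.0, size=1000)
        edges = freedman_diaconis_bins(y)
        width = 2.0 * (np.percentile(y, 75) - np.percentile(y, 25)) * 1000 ** (-1 / 3)
        assert len(edges) - 1 == int(np.ceil((y.max() - y.min()) / width))

    def test_bimodal_outputs_cover_both_modes(self, rng):
        y = np.concatenate([rng.normal(-5, 0.1, 500), rng.normal(5, 0.1, 500)])
        X = rng.normal(size=(1000, 2))
        train, _, _ = stratified_split(LabelledDataset(X, y), (100, 10, 10), seed=1)
        assert (train.y < 0).sum() >= 40
        assert (train.y > 0).sum() >= 40

    def test_disjoint_and_reproducible(self, rng):
        ds = LabelledDataset(rng.normal(size=(1400, 3)), rng.normal(size=1400))
        parts = stratified_split(ds, (200, 100, 1000), seed=11)
        ids = [set(p.geometry_ids) for p in parts]
        assert [len(p) for p in parts] == [200, 100, 1000]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        parts2 = stratified_split(ds, (200, 100, 1000), seed=11)
        for p, q in zip(parts, parts2):
            assert np.array_equal(p.X, q.X) and np.array_equal(p.y, q.y)

    def test_oversubscription_rejected(self, rng):
        ds = LabelledDataset(rng.normal(size=(10, 1)), rng.normal(size=10))
        with pytest.raises(ValueError):
            stratified_split(ds, (8, 2, 1), seed=0)


class TestSCurve:
    def test_perfect_model_flat_zero(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        model = fit(LabelledDataset(X, y), Hyperparameters(np.ones(2), 1e-12))
        curve = s_curve(model, LabelledDataset(X, y))
        assert np.all(curve.errors < 1e-6)

    def test_sorting_and_percentiles(self, rng):
        X = rng.normal(size=(3, 1))
        model = fit(LabelledDataset(X, [0.0, 0.0, 0.0]), Hyperparameters([1.0]))
        external = LabelledDataset(np.full((3, 1), 50.0), [1.0, 3.0, 2.0])
        curve = s_curve(model, external)  # predicts mean 0 -> errors |y|
        assert np.allclose(curve.errors, [1.0, 2.0, 3.0])
        assert np.allclose(curve.percentiles, [100 / 3, 200 / 3, 100.0])


def test_model_archive_roundtrip(tmp_path, rng):
    """A saved model reproduces predictions bit-for-bit after reload."""
    ds = LabelledDataset(rng.normal(size=(6, 3)), rng.normal(size=6))
    model = fit(ds, Hyperparameters([0.5, 1.0, 2.0], 1e-10),
                cyclic=np.array([False, False, True]),
                meta={"property": "energy/0", "alf": [(0, 1, 2)]})
    path = tmp_path / "model.json"
    gpr.save_model(model, path)
    back = gpr.load_model(path)
    x = rng.normal(size=3)
    assert predict(back, x) == predict(model, x)
    assert back.meta["property"] == "energy/0"
    (tmp_path / "junk.json").write_text("{}")
    with pytest.raises(ValueError, match="archive"):
        gpr.load_model(tmp_path / "junk.json")
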