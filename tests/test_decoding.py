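"""Feature extraction, shrinkage LDA (with oracles), sliding CV accuracy."""

import numpy as np
import pytest

from mrcpkit.data import ChannelInfo, EpochSet
from mrcpkit.decoding import (
    FeatureWindowConfig,
    confusion_at,
    extract_features,
    fit_slda,
    predict_proba,
    sliding_accuracy,
)

RATE = 256.0


def make_epochs(data, labels, t0=-2.0, channels=None):
    n_tr, n_ch, _ = data.shape
    chans = channels or [
        ChannelInfo(name=f"c{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_ch)
    ]
    return EpochSet(
        data=data, rate=RATE, t0_offset=t0, channels=chans,
        labels=np.asarray(labels, dtype=object),
    )


class TestFeatureWindow:
    def test_lag_count_arithmetic(self):
        cfg = FeatureWindowConfig(length=1.4, lag_spacing=0.2)
        assert cfg.n_lags == 8
        assert FeatureWindowConfig(length=0.0).n_lags == 1

    def test_center_vs_causal_offsets(self):
        c = FeatureWindowConfig(length=1.4, alignment="center").lag_offsets()
        np.testing.assert_allclose(c, np.arange(-0.7, 0.71, 0.2))
        k = FeatureWindowConfig(length=1.4, alignment="causal").lag_offsets()
        assert k.max() == pytest.approx(0.0) and k.min() == pytest.approx(-1.4)

    def test_feature_count_with_61_channels(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 61, int(5 * RATE)))
        eps = make_epochs(data, ["a", "b", "a"])
        X = extract_features(eps, 0.0, FeatureWindowConfig(length=1.4))
        assert X.shape == (3, 488)  # 61 channels x 8 lags

    def test_zero_length_single_sample(self):
        data = np.random.default_rng(1).normal(size=(2, 4, 256))
        eps = make_epochs(data, ["a", "b"], t0=0.0)
        X = extract_features(eps, 0.5, FeatureWindowConfig(length=0.0))
        assert X.shape == (2, 4)
        np.testing.assert_array_equal(X, data[:, :, 128])

    def test_identical_trials_identical_rows(self):
        one = np.random.default_rng(2).normal(size=(1, 3, 512))
        data = np.concatenate([one, one])
        eps = make_epochs(data, ["a", "b"], t0=0.0)
        X = extract_features(eps, 1.0, FeatureWindowConfig(length=0.4))
        np.testing.assert_array_equal(X[0], X[1])

    def test_bad_and_eog_channels_excluded(self):
        data = np.random.default_rng(3).normal(size=(2, 3, 256))
        chans = [
            ChannelInfo(name="good", kind="EEG", position=(0, 0)),
            ChannelInfo(name="bad", kind="EEG", position=(1, 0), is_bad=True),
            ChannelInfo(name="EOG1", kind="EOG"),
        ]
        eps = make_epochs(data, ["a", "b"], t0=0.0, channels=chans)
        X = extract_features(eps, 0.5, FeatureWindowConfig(length=0.0))
        assert X.shape == (2, 1)

    def test_lag_outside_epoch_names_the_lag(self):
        data = np.zeros((2, 2, 256))
        eps = make_epochs(data, ["a", "b"], t0=0.0)
        with pytest.raises(ValueError, match="lag"):
            extract_features(eps, 0.1, FeatureWindowConfig(length=1.4))


def _gaussian_classes(rng, n_per, d, sep, k=2):
    means = np.zeros((k, d))
    for j in range(k):
        means[j, j % d] = sep * j
    X = np.vstack([rng.normal(means[j], 1.0, size=(n_per, d)) for j in range(k)])
    y = np.repeat([f"cls{j}" for j in range(k)], n_per)
    return X, y


class TestSLDA:
    def test_separated_classes_high_heldout_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _gaussian_classes(rng, 200, 5, sep=10.0)
        Xt, yt = _gaussian_classes(rng, 500, 5, sep=10.0)
        model = fit_slda(X, y)
        assert np.mean(model.predict(Xt) == yt) > 0.99

    def test_lambda_zero_matches_direct_inversion_oracle(self):
        rng = np.random.default_rng(1)
        X, y = _gaussian_classes(rng, 400, 4, sep=2.0, k=3)
        model = fit_slda(X, y, shrinkage=0.0)
        # independent oracle: classical LDA scores via explicit inverse
        classes, y_idx = np.unique(y, return_inverse=True)
        means = np.stack([X[y_idx == j].mean(axis=0) for j in range(3)])
        centred = X - means[y_idx]
        cov = centred.T @ centred / len(X)
        inv = np.linalg.inv(cov)
        W = inv @ means.T
        b = -0.5 * np.einsum("kd,dk->k", means, W) + np.log(1 / 3)
        np.testing.assert_allclose(model.weights, W, rtol=1e-8)
        np.testing.assert_allclose(model.biases, b, rtol=1e-8)

    def test_lambda_one_is_nearest_mean_classifier(self):
        rng = np.random.default_rng(2)
        X, y = _gaussian_classes(rng, 50, 6, sep=3.0, k=3)
        model = fit_slda(X, y, shrinkage=1.0)
        Xt = rng.normal(size=(200, 6))
        classes, y_idx = np.unique(y, return_inverse=True)
        means = np.stack([X[y_idx == j].mean(axis=0) for j in range(3)])
        d2 = ((Xt[:, None, :] - means[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(model.predict(Xt), classes[np.argmin(d2, axis=1)])

    def test_singular_at_lambda_zero_raises(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 50))  # n << d
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_slda(X, y, shrinkage=0.0)

    def test_analytic_shrinkage_in_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = _gaussian_classes(rng, 30, 40, sep=1.0)
        m1 = fit_slda(X, y)
        m2 = fit_slda(X, y)
        assert 0.0 < m1.shrinkage <= 1.0
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            fit_slda(np.zeros((4, 0)), np.array(["a", "a", "b", "b"]))
        with pytest.raises(ValueError):
            fit_slda(np.zeros((4, 2)), np.array(["a"] * 4))
        with pytest.raises(ValueError):
            fit_slda(np.zeros((3, 2)), np.array(["a", "a", "b"]))


class TestPredictProba:
    def _model(self, seed=0):
        rng = np.random.default_rng(seed)
        X, y = _gaussian_classes(rng, 50, 3, sep=4.0)
        return fit_slda(X, y), X, y

    def test_rows_sum_to_one(self):
        model, X, _ = self._model()
        P = predict_proba(model, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_class_mean_gets_max_probability(self):
        model, _, _ = self._model()
        P = predict_proba(model, model.means)
        assert list(np.argmax(P, axis=1)) == [0, 1]

    def test_equidistant_point_is_fifty_fifty(self):
        # symmetric two-class problem with equal priors and forced lambda=1
        X = np.array([[-1.0, 0.0], [-1.1, 0.0], [1.0, 0.0], [1.1, 0.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_slda(X, y, shrinkage=1.0)
        P = predict_proba(model, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(P[0], [0.5, 0.5], atol=1e-9)

    def test_softmax_shift_invariance(self):
        model, X, _ = self._model()
        P1 = predict_proba(model, X)
        model.biases = model.biases + 123.4  # constant shift of all scores
        P2 = predict_proba(model, X)
        np.testing.assert_allclose(P1, P2, atol=1e-12)

    def test_dimension_mismatch(self):
        model, _, _ = self._model()
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((1, 99)))


def _template_epochs(rng, n_per_class=24, n_ch=6, sep=3.0, n_classes=3):
    """Class-specific bump templates + white noise, 5 s epochs at -2..3 s."""
    n_samp = int(5 * RATE)
    t = -2.0 + np.arange(n_samp) / RATE
    data, labels = [], []
    for j in range(n_classes):
        tmpl = np.zeros((n_ch, n_samp))
        bump = np.exp(-((t - 1.0) ** 2) / 0.1)
        for c in range(n_ch):
            tmpl[c] = sep * (j + 1) * bump * (1.0 if c % 2 else 0.5)
        for _ in range(n_per_class):
            data.append(tmpl + rng.normal(0, 1.0, size=(n_ch, n_samp)))
            labels.append(f"k{j}")
    return make_epochs(np.stack(data), labels)


class TestSlidingAccuracy:
    def test_null_data_fluctuates_around_chance(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(100, 4, int(5 * RATE)))
        labels = np.repeat([f"k{j}" for j in range(5)], 20)
        eps = make_epochs(data, labels)
        curve = sliding_accuracy(
            eps, FeatureWindowConfig(length=0.4), folds=5, repeats=2, seed=0,
            times=np.array([0.0, 1.0]),
        )
        assert np.all(curve.accuracy < 35.0) and np.all(curve.accuracy > 5.0)

    def test_informative_data_peaks_at_template_time(self):
        rng = np.random.default_rng(1)
        eps = _template_epochs(rng)
        curve = sliding_accuracy(
            eps, FeatureWindowConfig(length=0.4), folds=6, repeats=1, seed=0,
            times=np.array([-1.0, 1.0]),
        )
        assert curve.accuracy[1] > 80.0 and curve.accuracy[0] < 60.0
        t_pk, a_pk = curve.peak()
        assert t_pk == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        eps = _template_epochs(rng, n_per_class=12)
        kw = dict(folds=4, repeats=2, times=np.array([1.0]))
        a = sliding_accuracy(eps, FeatureWindowConfig(length=0.2), seed=9, **kw)
        b = sliding_accuracy(eps, FeatureWindowConfig(length=0.2), seed=9, **kw)
        np.testing.assert_array_equal(a.per_fold, b.per_fold)

    def test_affine_invariance_rescale_and_channel_order(self):
        rng = np.random.default_rng(3)
        eps = _template_epochs(rng, n_per_class=12)
        kw = dict(folds=4, repeats=1, seed=5, times=np.array([1.0]))
        cfg = FeatureWindowConfig(length=0.4)
        base = sliding_accuracy(eps, cfg, **kw)
        scaled = make_epochs(eps.data * 3.7, eps.labels)
        perm = [3, 1, 0, 2, 5, 4]
        permuted = make_epochs(eps.data[:, perm, :], eps.labels)
        np.testing.assert_allclose(
            sliding_accuracy(scaled, cfg, **kw).accuracy, base.accuracy, atol=1e-9
        )
        np.testing.assert_allclose(
            sliding_accuracy(permuted, cfg, **kw).accuracy, base.accuracy, atol=1e-9
        )

    def test_window_length_sweep_saturates(self):
        """Longer feature windows help then plateau when information is spread
        over time (class-dependent latency and amplitude)."""
        rng = np.random.default_rng(4)
        n_samp = int(5 * RATE)
        t = -2.0 + np.arange(n_samp) / RATE
        data, labels = [], []
        for j in range(3):
            tmpl = 1.2 * (j + 1) * np.exp(-((t - (0.7 + 0.3 * j)) ** 2) / 0.5)
            for _ in range(20):
                data.append(np.tile(tmpl, (4, 1)) + rng.normal(0, 1.0, (4, n_samp)))
                labels.append(f"k{j}")
        eps = make_epochs(np.stack(data), labels)
        accs = []
        for length in (0.0, 0.4, 0.8, 1.4):
            c = sliding_accuracy(
                eps, FeatureWindowConfig(length=length), folds=5, repeats=2,
                seed=0, times=np.array([1.0]),
            )
            accs.append(c.accuracy[0])
        assert accs[1] >= accs[0]  # lags add information at first
        assert accs[-1] >= accs[0]
        assert abs(accs[3] - accs[2]) <= 5.0  # plateau: little further gain

    def test_fold_count_error(self):
        rng = np.random.default_rng(5)
        eps = _template_epochs(rng, n_per_class=4)
        with pytest.raises(ValueError, match="fold"):
            sliding_accuracy(eps, FeatureWindowConfig(length=0.2), folds=10,
                             times=np.array([1.0]))


class TestConfusion:
    def test_perfect_separation_identity(self):
        rng = np.random.default_rng(0)
        eps = _template_epochs(rng, n_per_class=20, sep=30.0)
        classes, M = confusion_at(
            eps, FeatureWindowConfig(length=0.2), 1.0, folds=5, repeats=1
        )
        np.testing.assert_allclose(M, 100.0 * np.eye(3), atol=1e-9)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        eps = _template_epochs(rng, n_per_class=12, sep=0.5)
        _, M = confusion_at(
            eps, FeatureWindowConfig(length=0.2), 1.0, folds=4, repeats=2
        )
        np.testing.assert_allclose(M.sum(axis=1), 100.0, atol=1e-9)

    def test_overlapping_templates_confuse_each_other(self):
        """Classes sharing a template confuse mutually more than with distant ones."""
        rng = np.random.default_rng(2)
        n_samp = int(5 * RATE)
        t = -2.0 + np.arange(n_samp) / RATE
        bump = np.exp(-((t - 1.0) ** 2) / 0.1)
        data, labels = [], []
        scale = {"palmar": 4.00, "lateral": 4.35, "pronation": 12.0}
        for cls, s in scale.items():
            for _ in range(18):
                tr = np.tile(s * bump, (4, 1)) + rng.normal(0, 1.0, (4, n_samp))
                data.append(tr)
                labels.append(cls)
        eps = make_epochs(np.stack(data), labels)
        classes, M = confusion_at(
            eps, FeatureWindowConfig(length=0.2), 1.0, folds=6, repeats=2
        )
        i_p = list(classes).index("palmar")
        i_l = list(classes).index("lateral")
        i_r = list(classes).index("pronation")
        assert M[i_p, i_l] > M[i_p, i_r]
        assert M[i_l, i_p] > M[i_l, i_r]
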