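"""CNN track: architecture layout, backprop correctness, training behaviour."""

import numpy as np
import pytest

from relaxcell import AnnArchitecture, SplitSpec, SpectralCNN, build_ann, replicate_runs, train_ann
from relaxcell.nn import (
    Adamax,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    ReLU,
    SequentialNet,
    cross_entropy,
    softmax,
)


def blob_cohort(rng, centers, n_per_class, grids, width=0.18, jitter=0.03, n_aug=0):
    """Well-separated blob spectra, optionally with augmented descendants."""
    from relaxcell import AugmentationParams, Spectrum2D, augment_spectrum

    t1g, t2g = grids
    x_, y_ = np.log(t1g)[:, None], np.log(t2g)[None, :]
    spectra = []
    for label, (c1, c2) in centers.items():
        for i in range(n_per_class):
            j1 = c1 * 10 ** rng.normal(0, jitter)
            j2 = c2 * 10 ** rng.normal(0, jitter)
            inten = np.exp(-((x_ - np.log(j1)) ** 2 + (y_ - np.log(j2)) ** 2) / (2 * width**2))
            spec = Spectrum2D(t1g, t2g, inten, sample_id=f"{label}{i}", class_label=label)
            if n_aug:
                spectra.extend(
                    augment_spectrum(spec, AugmentationParams(factor=n_aug, seed=i))
                )
            else:
                spectra.append(spec)
    return spectra


SMALL = dict(input_size=(32, 32), base_channels=4, dense_widths=(32, 16, 8))


class TestArchitecture:
    def test_msc_variant_layer_counts(self):
        arch = AnnArchitecture(variant="msc", **SMALL)
        assert arch.conv_layers == 7 and arch.dense_layers == 4
        net = build_ann(arch, n_classes=3)
        counts = net.layer_counts()
        assert counts["Conv2D"] == 7
        assert counts["Dense"] == 4
        assert counts["MaxPool2"] == 4
        assert "Dropout" not in counts

    def test_cell_line_variant_layer_counts_and_dropout(self):
        arch = AnnArchitecture(variant="cell_line", **SMALL)
        assert arch.dropout_rate == 0.25
        net = build_ann(arch, n_classes=4)
        counts = net.layer_counts()
        assert counts["Conv2D"] == 4
        assert counts["Dense"] == 4
        assert counts["MaxPool2"] == 4
        assert counts["Dropout"] == 3  # after each hidden dense layer

    def test_epochs_default_is_twelve(self):
        assert AnnArchitecture().epochs == 12

    def test_input_too_small_rejected(self):
        arch = AnnArchitecture(variant="msc", **SMALL)
        with pytest.raises(ValueError):
            build_ann(arch, n_classes=2, input_shape=(8, 8))

    def test_untrained_balanced_accuracy_is_chance(self, grids):
        rng = np.random.default_rng(0)
        k = 4
        centers = {c: (0.3 + 0.25 * i, 0.03 + 0.04 * i) for i, c in enumerate("ABCD")}
        spectra = blob_cohort(rng, centers, 10, grids)
        from relaxcell.classify import spectra_to_images

        images = spectra_to_images(spectra, (32, 32))
        labels = np.repeat(np.arange(k), 10)
        accs = [
            (build_ann(AnnArchitecture(variant="cell_line", **SMALL), k, seed=s).predict(images) == labels).mean()
            for s in range(8)
        ]
        assert abs(np.mean(accs) - 1 / k) < 0.2


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = SequentialNet(
            [
                Conv2D(1, 2, rng=rng),
                BatchNorm(2),
                ReLU(),
                MaxPool2(),
                Flatten(),
                Dense(2 * 4 * 4, 3, rng=rng),
            ]
        )
        # promote parameters to float64 so finite differences are clean;
        # ReLU/MaxPool kink crossings can still produce isolated outliers
        for layer in net.layers:
            for i, p in enumerate(layer.params):
                layer.params[i] = p.astype(np.float64)
            if isinstance(layer, (Conv2D, Dense)):
                layer.w, layer.b = layer.params
            if isinstance(layer, BatchNorm):
                layer.gamma, layer.beta = layer.params
                layer.run_mean = layer.run_mean.astype(np.float64)
                layer.run_var = layer.run_var.astype(np.float64)
            layer.grads = [np.zeros_like(p) for p in layer.params]
        x = rng.normal(size=(4, 8, 8, 1))
        y = np.array([0, 1, 2, 0])

        def loss():
            return cross_entropy(softmax(net.forward(x, train=True)), y)

        probs = softmax(net.forward(x, train=True))
        g = probs.copy()
        g[np.arange(4), y] -= 1.0
        g = g / 4
        for layer in reversed(net.layers):
            g = layer.backward(g)
        eps = 1e-6
        rel_errors = []
        for layer in net.layers:
            for p, grad in zip(layer.params, layer.grads):
                flat_p, flat_g = p.ravel(), grad.ravel()
                for idx in rng.choice(flat_p.size, size=min(6, flat_p.size), replace=False):
                    orig = flat_p[idx]
                    flat_p[idx] = orig + eps
                    hi = loss()
                    flat_p[idx] = orig - eps
                    lo = loss()
                    flat_p[idx] = orig
                    numeric = (hi - lo) / (2 * eps)
                    rel_errors.append(
                        abs(numeric - flat_g[idx]) / max(1e-8, abs(numeric), abs(flat_g[idx]))
                    )
        rel_errors = np.array(rel_errors)
        assert rel_errors.size >= 20
        assert np.median(rel_errors) < 1e-6
        assert (rel_errors < 1e-4).mean() >= 0.9  # allow rare kink crossings
        assert rel_errors.max() < 0.2

    def test_adamax_step_decreases_loss_on_fixed_batch(self):
        rng = np.random.default_rng(1)
        net = SequentialNet([Flatten(), Dense(16, 8, rng=rng), ReLU(), Dense(8, 2, rng=rng)])
        opt = Adamax(lr=1e-2)
        x = rng.normal(size=(8, 4, 4, 1)).astype(np.float32)
        y = np.array([0, 1] * 4)
        losses = [net.train_batch(x, y, opt) for _ in range(30)]
        assert losses[-1] < losses[0]


class TestTraining:
    def test_separable_cohort_learns(self, grids):
        rng = np.random.default_rng(0)
        spectra = blob_cohort(rng, {"A": (0.4, 0.04), "B": (1.2, 0.15)}, 30, grids)
        arch = AnnArchitecture(variant="cell_line", **SMALL)
        report = train_ann(spectra, arch, SplitSpec(), seed=1)
        assert report.test_accuracy >= 0.95
        assert report.epoch_loss[-1] < report.epoch_loss[0]
        assert len(report.epoch_loss) == 12

    def test_confusion_matrix_conserves_test_counts(self, grids):
        rng = np.random.default_rng(0)
        spectra = blob_cohort(rng, {"A": (0.4, 0.04), "B": (1.2, 0.15)}, 20, grids)
        arch = AnnArchitecture(variant="cell_line", epochs=2, **SMALL)
        report = train_ann(spectra, arch, SplitSpec(), seed=1)
        assert report.confusion.sum() == report.n_test
        assert report.confusion.sum(axis=1).tolist() == [5, 5]

    def test_deterministic_given_seed(self, grids):
        rng = np.random.default_rng(0)
        spectra = blob_cohort(rng, {"A": (0.4, 0.04), "B": (1.2, 0.15)}, 8, grids)
        arch = AnnArchitecture(variant="cell_line", epochs=2, **SMALL)
        a = train_ann(spectra, arch, SplitSpec(), seed=5)
        b = train_ann(spectra, arch, SplitSpec(), seed=5)
        assert a.epoch_loss == b.epoch_loss
        assert a.test_accuracy == b.test_accuracy

    def test_replicate_aggregation(self, grids):
        rng = np.random.default_rng(0)
        spectra = blob_cohort(rng, {"A": (0.4, 0.04), "B": (1.2, 0.15)}, 10, grids)
        arch = AnnArchitecture(variant="cell_line", epochs=2, **SMALL)
        agg = replicate_runs(
            lambda s, i: train_ann(spectra, arch, SplitSpec(), seed=s, replicate_index=i),
            n_replicates=3,
            seed=7,
        )
        assert len(agg.reports) == 3
        assert agg.mean_accuracy == pytest.approx(agg.accuracies.mean())
        # averaged confusion row sums equal mean per-class test counts
        np.testing.assert_allclose(
            agg.mean_confusion.sum(axis=1),
            np.mean([r.confusion.sum(axis=1) for r in agg.reports], axis=0),
        )

    def test_spectral_cnn_model_interface(self, grids):
        rng = np.random.default_rng(0)
        spectra = blob_cohort(rng, {"A": (0.4, 0.04), "B": (1.2, 0.15)}, 8, grids, n_aug=2)
        model = SpectralCNN(spectra, AnnArchitecture(variant="msc", epochs=2, **SMALL))
        report = model.fit(seed=2)
        assert 0.0 <= report.test_accuracy <= 1.0
        assert "test accuracy" in report.summary()
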