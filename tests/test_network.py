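"""Graph-convolutional classifier: architecture audit, forward contracts,
Dice loss, training behavior and checkpointing."""

from dataclasses import replace

import numpy as np
import pytest

from chebseg import (GraphSample, NetworkConfig, build_model, cross_validate,
                     dice_loss, fine_tune_tumor, forward, load_model,
                     parameter_counts, predict_mask, save_model, train)


@pytest.mark.parametrize("k", [1, 2, 3, 5])
def test_parameter_counts_match_architecture_formulas(k):
    """ChebConv 16->16 has 256K+16 parameters, each batch norm 32, and the
    final 16->2 convolution 32K+2, for any configured order K."""
    config = NetworkConfig(cheb_orders=(k, k, k, k))
    counts = parameter_counts(build_model(config))
    for i in (1, 2, 3):
        assert counts[f"cheb_conv_{i}"] == 256 * k + 16
        assert counts[f"batch_norm_{i}"] == 32
    assert counts["cheb_conv_4"] == 32 * k + 2
    assert counts["softmax"] == 0


class TestForward:
    def test_rows_are_probabilities(self, liver_sample, tiny_config):
        probs = forward(build_model(tiny_config), liver_sample)
        assert probs.shape == (liver_sample.partition.region_count, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, liver_sample, tiny_config):
        model = build_model(tiny_config)
        a = forward(model, liver_sample, training=False)
        b = forward(model, liver_sample, training=False)
        assert np.array_equal(a, b)

    def test_dropout_only_active_in_training(self, liver_sample):
        config = NetworkConfig(dropout_rate=0.5, seed=1)
        model = build_model(config)
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        t1 = forward(model, liver_sample, training=True, rng=rng1)
        t2 = forward(model, liver_sample, training=True, rng=rng2)
        assert not np.allclose(t1, t2)  # dropout masks differ
        zero_dropout = build_model(replace(config, dropout_rate=0.0))
        a = forward(zero_dropout, liver_sample, training=True,
                    rng=np.random.default_rng(1))
        b = forward(zero_dropout, liver_sample, training=True,
                    rng=np.random.default_rng(2))
        assert np.array_equal(a, b)

    def test_permutation_equivariance(self, liver_sample, tiny_config):
        model = build_model(tiny_config)
        base = forward(model, liver_sample, training=False)
        rng = np.random.default_rng(0)
        perm = rng.permutation(liver_sample.partition.region_count)
        permuted = GraphSample(
            graph=replace(liver_sample.graph,
                          features=liver_sample.graph.features[perm],
                          adjacency=liver_sample.graph.adjacency[np.ix_(perm, perm)],
                          weights=liver_sample.graph.weights[np.ix_(perm, perm)]),
            scaled_laplacian=liver_sample.scaled_laplacian[np.ix_(perm, perm)],
            node_labels=liver_sample.node_labels[perm],
            partition=liver_sample.partition,
            region_areas=liver_sample.region_areas[perm])
        out = forward(model, permuted, training=False)
        assert np.max(np.abs(out - base[perm])) <= 1e-6


class TestDiceLoss:
    def test_perfect_and_disjoint(self):
        y = np.array([1, 0, 1, 0])
        areas = np.ones(4)
        perfect = np.stack([1.0 - y, y.astype(float)], axis=1)
        assert dice_loss(perfect, y, areas) == pytest.approx(0.0, abs=1e-5)
        flipped = perfect[:, ::-1]
        assert dice_loss(flipped, y, areas) == pytest.approx(1.0, abs=1e-5)

    def test_uniform_half_positive_closed_form(self):
        y = np.array([1, 1, 0, 0])
        probs = np.full((4, 2), 0.5)
        assert dice_loss(probs, y, np.ones(4)) == pytest.approx(0.5, abs=1e-5)

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((2, 2), 0.5), np.array([0, 1]), np.zeros(2))


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, liver_sample):
        config = NetworkConfig(epochs=0, seed=5)
        init = build_model(config)
        out = train([liver_sample, liver_sample], config)
        for key in init.params:
            assert np.array_equal(out.params[key], init.params[key])

    def test_same_seed_gives_identical_history(self, liver_sample, tiny_config):
        a = train([liver_sample, liver_sample], tiny_config)
        b = train([liver_sample, liver_sample], tiny_config)
        assert a.history == b.history
        assert a.history["loss"][-1] < a.history["loss"][0]

    def test_can_overfit_single_sample(self, liver_sample):
        # capacity check: one step per epoch, so a larger step size is used
        config = NetworkConfig(epochs=200, seed=2, dropout_rate=0.0,
                               learning_rate=0.01, weight_decay=0.0)
        model = train([liver_sample], config, model=build_model(config))
        probs = forward(model, liver_sample, training=False)
        loss = dice_loss(probs, liver_sample.node_labels,
                         liver_sample.region_areas)
        assert loss < 0.05

    @pytest.mark.parametrize("name", ["adamax", "sgd", "rmsprop", "adadelta"])
    def test_alternative_optimizers_run_and_stay_finite(self, liver_sample, name):
        config = NetworkConfig(epochs=3, seed=4, optimizer_name=name)
        model = train([liver_sample, liver_sample], config)
        assert np.isfinite(model.history["loss"]).all()

    def test_fine_tune_zero_epochs_preserves_parameters(self, liver_sample,
                                                        tiny_config):
        liver_model = train([liver_sample, liver_sample], tiny_config)
        tuned = fine_tune_tumor(liver_model, [liver_sample],
                                replace(tiny_config, epochs=0))
        for key in liver_model.params:
            assert np.array_equal(tuned.params[key], liver_model.params[key])
        # history carried over
        assert tuned.history["loss"] == liver_model.history["loss"]

    def test_fine_tune_rejects_incompatible_architecture(self, liver_sample,
                                                         tiny_config):
        liver_model = train([liver_sample, liver_sample], tiny_config)
        other = replace(tiny_config, cheb_orders=(4, 4, 4, 4))
        with pytest.raises(ValueError):
            fine_tune_tumor(liver_model, [liver_sample], other)


class TestCrossValidate:
    def test_fold_partition_properties(self, normalized_slice):
        from chebseg import make_graph_sample

        ct, masks = normalized_slice
        samples = [make_graph_sample(ct, masks["liver"], n_regions=60)
                   for _ in range(6)]
        config = NetworkConfig(epochs=2, seed=3, folds=3)
        reports, mean = cross_validate(samples, config)
        assert len(reports) == 3
        assert 0.0 <= mean.accuracy <= 1.0
        with pytest.raises(ValueError):
            cross_validate(samples, replace(config, folds=1))
        with pytest.raises(ValueError):
            cross_validate(samples[:2], replace(config, folds=3))


class TestPredictAndCheckpoint:
    def test_predict_mask_composes_with_label_projection(self, normalized_slice,
                                                         tiny_config):
        ct, _ = normalized_slice
        model = build_model(tiny_config)
        mask, scores = predict_mask(model, ct, n_regions=60)
        assert mask.pixels.shape == ct.pixels.shape
        assert scores.min() >= 0 and scores.max() <= 1

    def test_checkpoint_round_trip(self, liver_sample, tiny_config, tmp_path):
        model = train([liver_sample, liver_sample], tiny_config)
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        assert loaded.config == model.config
        for key in model.params:
            assert np.array_equal(loaded.params[key], model.params[key])
        a = forward(model, liver_sample)
        b = forward(loaded, liver_sample)
        assert np.array_equal(a, b)

    def test_corrupt_checkpoint_raises_cleanly(self, tmp_path):
        (tmp_path / "bad.npz").write_bytes(b"junk")
        (tmp_path / "bad.json").write_text("{not json")
        with pytest.raises(IOError):
            load_model(tmp_path / "bad")
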