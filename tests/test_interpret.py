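"""Interpretability outputs: kernels, pooled activations, weighted outputs."""

import numpy as np
import pytest

from nirscnn.cnn import CNNConfig, forward, init_model, load_model, save_model
from nirscnn.data import FeatureSeries
from nirscnn.interpret import (
    build_bundle,
    export_kernels,
    most_discriminative_kernel,
    pooled_outputs,
    weighted_pooled_output,
    write_bundle,
)

CFG = CNNConfig(kernel_len=3, n_kernels=3, epochs=1)
N = 16


@pytest.fixture
def model():
    return init_model(CFG, N, seed=21)


@pytest.fixture
def dataset(rng):
    out = []
    for label in (0, 1):
        for i in range(3):
            out.append(FeatureSeries(rng.random(N) + 0.3 * label,
                                     channel="CH1", subject=f"s{label}{i}",
                                     label=label))
    return out


class TestExportKernels:
    def test_default_config_gives_9_profiles_of_10(self):
        m = init_model(CNNConfig(), 200, seed=0)
        profiles = export_kernels(m)
        assert profiles.shape == (9, 10)

    def test_untrained_model_profiles_equal_seeded_initialization(self, model):
        np.testing.assert_array_equal(
            export_kernels(model), init_model(CFG, N, seed=21).kernels)

    def test_round_trip_through_serialization(self, model, tmp_path):
        path = save_model(model, tmp_path / "m.json")
        np.testing.assert_array_equal(
            export_kernels(load_model(path)), export_kernels(model))

    def test_profiles_are_a_copy(self, model):
        export_kernels(model)[0, 0] = 99.0
        assert model.kernels[0, 0] != 99.0


class TestPooledOutputs:
    def test_single_subject_per_class_returns_activations_verbatim(
            self, model, dataset):
        small = [dataset[0], dataset[3]]
        out = pooled_outputs(model, small)
        for c, fs in ((0, small[0]), (1, small[1])):
            _, cache = forward(model, fs)
            np.testing.assert_allclose(out[:, c, :], cache["pooled"])

    def test_matches_independent_composition_per_subject(self, model, dataset):
        from nirscnn.cnn import activate, convolve, max_pool
        out = pooled_outputs(model, dataset)
        for c in (0, 1):
            members = [fs for fs in dataset if fs.label == c]
            recomputed = np.mean([
                max_pool(activate(convolve(fs.values, model.kernels),
                                  CFG.activation),
                         CFG.pool_len, CFG.pool_stride)
                for fs in members
            ], axis=0)
            np.testing.assert_allclose(out[:, c, :], recomputed, atol=1e-12)

    def test_pooled_length_matches_model(self, model, dataset):
        out = pooled_outputs(model, dataset)
        assert out.shape == (CFG.n_kernels, 2, model.pooled_len)

    def test_missing_class_rejected(self, model, dataset):
        with pytest.raises(ValueError):
            pooled_outputs(model, [fs for fs in dataset if fs.label == 0])


class TestWeightedPooledOutput:
    def test_unit_weights_reproduce_pooled_outputs(self, model, dataset):
        model.dense_w[:] = 1.0
        pooled = pooled_outputs(model, dataset)
        for k in (1, 2, 3):
            np.testing.assert_allclose(
                weighted_pooled_output(model, dataset, k, 1), pooled[k - 1])

    def test_zero_weights_give_zero_sequence(self, model, dataset):
        model.dense_w[:] = 0.0
        np.testing.assert_array_equal(
            weighted_pooled_output(model, dataset, 2, 0), 0.0)

    def test_matches_elementwise_loop(self, model, dataset):
        P = model.pooled_len
        pooled = pooled_outputs(model, dataset)
        for k in (1, CFG.n_kernels):
            for neuron in (0, 1):
                got = weighted_pooled_output(model, dataset, k, neuron)
                for c in (0, 1):
                    expected = [
                        pooled[k - 1, c, p]
                        * model.dense_w[neuron, (k - 1) * P + p]
                        for p in range(P)
                    ]
                    np.testing.assert_allclose(got[c], expected, atol=1e-12)

    def test_linear_in_dense_weights(self, model, dataset):
        base = weighted_pooled_output(model, dataset, 1, 1)
        model.dense_w *= 3.0
        np.testing.assert_allclose(
            weighted_pooled_output(model, dataset, 1, 1), 3.0 * base,
            atol=1e-12)

    def test_kernel_index_out_of_range_rejected(self, model, dataset):
        with pytest.raises(ValueError):
            weighted_pooled_output(model, dataset, 0, 1)
        with pytest.raises(ValueError):
            weighted_pooled_output(model, dataset, CFG.n_kernels + 1, 1)


class TestMostDiscriminativeKernel:
    def test_kernel_responding_to_class_difference_is_found(self, model, rng):
        # craft data where only kernel 2's pooled response differs by class:
        # zero out dense weights except kernel 2's block, and give classes
        # inputs that differ strongly
        P = model.pooled_len
        model.dense_w[:] = 0.0
        model.dense_w[1, P:2 * P] = 1.0
        data = [FeatureSeries(np.zeros(N) + lab * 2.0, channel="CH1",
                              subject=f"s{i}", label=lab)
                for i, lab in enumerate([0, 0, 1, 1])]
        idx, score = most_discriminative_kernel(model, data, output_neuron=1)
        assert idx == 2
        assert score > 0

    def test_identical_class_means_score_zero_tie_breaks_to_kernel_1(
            self, model):
        data = [FeatureSeries(np.full(N, 0.5), channel="CH1",
                              subject=f"s{i}", label=lab)
                for i, lab in enumerate([0, 0, 1, 1])]
        idx, score = most_discriminative_kernel(model, data)
        assert idx == 1
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_label_swap(self, model, dataset):
        idx, score = most_discriminative_kernel(model, dataset)
        swapped = [FeatureSeries(fs.values, channel=fs.channel,
                                 subject=fs.subject, label=1 - fs.label)
                   for fs in dataset]
        idx2, score2 = most_discriminative_kernel(model, swapped)
        assert idx == idx2
        assert score == pytest.approx(score2)

    def test_single_class_rejected(self, model, dataset):
        with pytest.raises(ValueError):
            most_discriminative_kernel(
                model, [fs for fs in dataset if fs.label == 1])


class TestBundle:
    def test_bundle_reproducible_from_serialized_model_and_data(
            self, model, dataset, tmp_path):
        bundle = build_bundle(model, dataset)
        reloaded = load_model(save_model(model, tmp_path / "m.json"))
        bundle2 = build_bundle(reloaded, dataset)
        np.testing.assert_array_equal(bundle.kernel_profiles,
                                      bundle2.kernel_profiles)
        np.testing.assert_array_equal(bundle.pooled_by_class,
                                      bundle2.pooled_by_class)
        np.testing.assert_array_equal(bundle.weighted_pooled,
                                      bundle2.weighted_pooled)
        assert bundle.best_kernel == bundle2.best_kernel

    def test_written_tables_and_metadata(self, model, dataset, tmp_path):
        import json
        bundle = build_bundle(model, dataset)
        meta_path = write_bundle(bundle, tmp_path)
        meta = json.loads(meta_path.read_text())
        assert meta["n_kernels"] == CFG.n_kernels
        assert meta["kernel_len"] == CFG.kernel_len
        assert (tmp_path / "kernels.tsv").exists()
        assert (tmp_path / "pooled.tsv").exists()
        assert (tmp_path / "weighted_pooled.tsv").exists()
        assert (tmp_path / "inputs_by_class.tsv").exists()
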