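import numpy as np
import pytest

from ecaleaf._layers import Dropout, GlobalAvgPool, ReLU6, Residual, Sequential
from ecaleaf.network import (
    BACKBONE_ROWS,
    NetworkSpec,
    build_network,
    count_parameters,
    expected_output_sizes,
    parameter_ledger,
    predict,
)

# output column of the architecture table at the 448-px input, stage by stage
TABLE_OUTPUT_SIZES = [
    (224, 224, 16),
    (112, 112, 16),
    (56, 56, 24), (56, 56, 24), (56, 56, 24),
    (28, 28, 40), (28, 28, 40), (28, 28, 40),
    (14, 14, 48), (14, 14, 48), (14, 14, 48),
    (7, 7, 48), (7, 7, 48), (7, 7, 48),
    (7, 7, 288),
    (1, 1, 288),
    (1, 1, 512),
    (1, 1, 512),
    (1, 1, 4),
]


class TestParameterCount:
    def test_full_variant(self):
        assert count_parameters(variant="full") == 418_181

    def test_no_eca_variant(self):
        assert count_parameters(variant="no_eca") == 418_148

    def test_attention_costs_33_scalars(self):
        assert count_parameters(variant="full") - count_parameters(variant="no_eca") == 33

    def test_dropout_is_parameter_free(self):
        assert count_parameters(variant="no_dropout") == count_parameters(variant="full")

    def test_total_rounds_to_0418m(self):
        assert round(count_parameters() / 1e6, 3) == 0.418

    @pytest.mark.parametrize("variant", ["full", "no_eca", "no_dropout"])
    def test_closed_form_matches_built_network(self, variant):
        net = build_network(variant=variant, seed=0)
        assert net.parameter_count() == count_parameters(variant=variant)

    def test_ledger_rows_sum_to_total(self):
        rows, total = parameter_ledger()
        assert sum(c for _, c in rows) == total == 418_181
        assert len(rows) == 1 + len(BACKBONE_ROWS) + 3

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            count_parameters(variant="no_bn")


class TestShapes:
    def test_expected_trace_matches_architecture_table(self):
        assert expected_output_sizes() == TABLE_OUTPUT_SIZES

    def test_forward_activations_match_table(self):
        """Every stage's activation at a 448x448x3 input has the tabled size."""
        net = build_network(seed=0)
        x = np.random.default_rng(0).normal(size=(1, 3, 448, 448)).astype(np.float32)
        shapes = []
        for layer in net.stack.layers:
            x = layer.forward(x, False)
            # record once per table row: after each activation, block, pool, dropout
            if isinstance(layer, (Sequential, Residual, GlobalAvgPool, Dropout, ReLU6)):
                shapes.append((x.shape[2], x.shape[3], x.shape[1]))
        shapes.append((x.shape[2], x.shape[3], x.shape[1]))  # final classifier conv
        assert shapes == TABLE_OUTPUT_SIZES

    def test_wrong_input_shape_reported(self):
        net = build_network(seed=0)
        with pytest.raises(ValueError, match="448"):
            net.forward(np.zeros((1, 3, 64, 64), np.float32))

    def test_scaled_input_contract(self):
        spec = NetworkSpec(input_size=64)
        net = build_network(spec, seed=0)
        out = net.forward(np.zeros((2, 3, 64, 64), np.float32))
        assert out.shape == (2, 4)


class TestPredict:
    def test_zero_network_gives_uniform_scores(self):
        net = build_network(NetworkSpec(input_size=64), init="zeros")
        labels, scores = predict(net, np.zeros((3, 3, 64, 64), np.float32))
        np.testing.assert_allclose(scores, 0.25, atol=1e-7)
        assert labels.shape == (3,)

    def test_scores_sum_to_one(self, rng):
        net = build_network(NetworkSpec(input_size=64), seed=3)
        _, scores = predict(net, rng.normal(size=(4, 3, 64, 64)).astype(np.float32))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, rtol=1e-6)

    def test_empty_batch_rejected(self):
        net = build_network(NetworkSpec(input_size=64), seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((0, 3, 64, 64), np.float32))


class TestDeterminismAndVariants:
    def test_eval_forward_is_bit_identical(self, rng):
        net = build_network(NetworkSpec(input_size=64), seed=5)
        x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_no_dropout_eval_equals_full_eval(self, rng):
        x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        full = build_network(NetworkSpec(input_size=64), "full", seed=7)
        nodrop = build_network(NetworkSpec(input_size=64), "no_dropout", seed=7)
        np.testing.assert_array_equal(full.forward(x), nodrop.forward(x))

    def test_no_eca_has_no_gates(self):
        from ecaleaf.attention import EcaGate
        from ecaleaf.network import _iter_layers

        net = build_network(variant="no_eca", seed=0)
        assert not any(isinstance(l, EcaGate) for l in _iter_layers(net.stack))
        full = build_network(variant="full", seed=0)
        assert sum(isinstance(l, EcaGate) for l in _iter_layers(full.stack)) == 11


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        from ecaleaf.network import Network

        net = build_network(NetworkSpec(input_size=64), seed=9)
        x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
        before = net.forward(x)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = Network.load(path)
        np.testing.assert_array_equal(loaded.forward(x), before)

    def test_architecture_mismatch_rejected(self, tmp_path):
        from ecaleaf.network import Network

        net = build_network(NetworkSpec(input_size=64), seed=0)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        with pytest.raises(ValueError, match="architecture"):
            Network.load(path, spec=NetworkSpec(input_size=448))
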