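"""Full-network assembly: splitting, fusion, the spiking classifier, the
ANN twin, ablations, gradient flow, and checkpoint round-trips."""

from dataclasses import replace

import numpy as np
import pytest

from mfsnn.lif import LIFParams, lif_run, rate_encode, spike_rate
from mfsnn.model import (
    ConfigError,
    MFSNN,
    ModelConfig,
    ablate,
    build_mfann,
    classify,
    concat_features,
    load_checkpoint,
    save_checkpoint,
    split_channels,
)
from mfsnn.sub_encoder import encode
from mfsnn.training import softmax_cross_entropy


class TestSplitConcat:
    def test_reference_configuration_128_into_16(self):
        blocks = split_channels(np.zeros((128, 20)), 16)
        assert len(blocks) == 16
        assert all(b.shape == (8, 20) for b in blocks)

    def test_single_block_is_identity(self):
        x = np.random.default_rng(0).standard_normal((6, 4))
        blocks = split_channels(x, 1)
        np.testing.assert_array_equal(blocks[0], x)

    def test_indivisible_split_names_both_values(self):
        with pytest.raises(ConfigError, match="100.*16"):
            split_channels(np.zeros((100, 20)), 16)

    @pytest.mark.parametrize("nc,ns", [(128, 16), (192, 16), (16, 2), (8, 8)])
    def test_round_trip_exact(self, nc, ns):
        x = np.random.default_rng(1).standard_normal((nc, 10))
        np.testing.assert_array_equal(concat_features(split_channels(x, ns)), x)

    def test_two_constant_blocks_stack_in_order(self):
        a, b = np.full((2, 3), 1.0), np.full((2, 3), 2.0)
        out = concat_features([a, b])
        assert out.shape == (4, 3)
        np.testing.assert_array_equal(out[:2], a)
        np.testing.assert_array_equal(out[2:], b)

    def test_ragged_blocks_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            concat_features([np.zeros((2, 3)), np.zeros((2, 4))])


class TestClassify:
    def test_zero_feature_yields_bias_logits(self):
        bias = np.array([0.3, -0.1, 0.5])
        out = classify(np.zeros((4, 5)), np.zeros((3, 20)), bias, LIFParams())
        np.testing.assert_array_equal(out, bias)

    def test_four_logits_for_grasp_touch(self):
        rng = np.random.default_rng(2)
        out = classify(
            rng.uniform(0, 1, (8, 5)), rng.standard_normal((4, 40)), np.zeros(4),
            LIFParams(),
        )
        assert out.shape == (4,)

    def test_equals_hand_computed_rates_times_weights(self):
        rng = np.random.default_rng(3)
        e_out = rng.uniform(0, 1.2, (4, 5))
        W = rng.standard_normal((3, 20))
        b = rng.standard_normal(3)
        lif = LIFParams()
        rates = spike_rate(lif_run(rate_encode(e_out.reshape(-1), lif), lif))
        np.testing.assert_allclose(classify(e_out, W, b, lif), W @ rates + b)


class TestModelConfig:
    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig.build(n_channels=100, n_subencoders=16)

    def test_dropping_both_time_branches_rejected(self):
        with pytest.raises(ConfigError, match="time-resolved"):
            ModelConfig.build(n_channels=16, n_subencoders=2, use_tcn=False, use_lt=False)

    def test_dict_round_trip(self, tiny_config):
        assert ModelConfig.from_dict(tiny_config.to_dict()) == tiny_config


class TestForward:
    def test_logit_shape_and_determinism(self, tiny_model, tiny_batch):
        a = tiny_model.forward(tiny_batch)
        b = tiny_model.forward(tiny_batch)
        assert a.shape == (6, 4)
        np.testing.assert_array_equal(a, b)

    def test_zero_input_zero_params_bias_logits(self, tiny_config):
        m = MFSNN(tiny_config)
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        m.params["clf_b"] = np.array([0.1, 0.2, 0.3, 0.4])
        logits = m.forward(np.zeros((2, 16, 20)))
        np.testing.assert_allclose(logits, np.tile([0.1, 0.2, 0.3, 0.4], (2, 1)))

    def test_matches_single_trial_functional_composition(self, tiny_model):
        """Batched network path == per-trial sub_encoder/classify oracles."""
        rng = np.random.default_rng(7)
        x = rng.poisson(1.0, (3, 16, 20)).astype(float)
        logits = tiny_model.forward(x)
        cfg = tiny_model.config
        for trial in range(3):
            blocks = split_channels(x[trial], cfg.n_subencoders)
            feats = []
            for i, block in enumerate(blocks):
                params = {
                    "Ml": tiny_model.params[f"enc{i}/Ml"],
                    "tcn_w": tiny_model.params[f"enc{i}/tcn_w"],
                    "tcn_b": tiny_model.params[f"enc{i}/tcn_b"],
                    "ca_W1": tiny_model.params[f"enc{i}/ca_W1"],
                    "ca_b1": tiny_model.params[f"enc{i}/ca_b1"],
                    "ca_W2": tiny_model.params[f"enc{i}/ca_W2"],
                    "ca_b2": tiny_model.params[f"enc{i}/ca_b2"],
                }
                feats.append(encode(block, params, cfg.sub_encoder))
            e_out = concat_features(feats)
            expected = classify(
                e_out, tiny_model.params["clf_W"], tiny_model.params["clf_b"],
                cfg.classifier_lif,
            )
            np.testing.assert_allclose(logits[trial], expected, atol=1e-12)

    def test_argmax_tie_breaks_to_lowest_index(self, tiny_config):
        m = MFSNN(tiny_config)
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        assert m.predict(np.zeros((1, 16, 20)))[0] == 0


class TestGradients:
    def test_every_parameter_group_receives_finite_nonzero_gradient(
        self, tiny_model, tiny_batch
    ):
        labels = np.array([0, 1, 2, 3, 0, 1])
        logits = tiny_model.forward(tiny_batch, want_cache=True)
        _, d_logits = softmax_cross_entropy(logits, labels)
        grads = tiny_model.backward(d_logits)
        assert set(grads) == set(tiny_model.params)
        for key, g in grads.items():
            assert np.isfinite(g).all(), key
        nonzero = [k for k, g in grads.items() if np.abs(g).sum() > 0]
        # every branch participates: LT, TCN, CA bottleneck, classifier
        assert any("Ml" in k for k in nonzero)
        assert any("tcn_w" in k for k in nonzero)
        assert any("ca_W" in k for k in nonzero)
        assert "clf_W" in nonzero

    def test_ann_backward_matches_finite_differences(self, tiny_config):
        """In ANN mode the network is truly differentiable, so the shared
        backward machinery can be checked against central differences."""
        m = build_mfann(replace(tiny_config, seed=5))
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 2.0, (4, 16, 20))
        labels = np.array([0, 1, 2, 3])

        def loss_fn():
            return softmax_cross_entropy(m.forward(x), labels)[0]

        logits = m.forward(x, want_cache=True)
        _, d_logits = softmax_cross_entropy(logits, labels)
        grads = m.backward(d_logits)
        rng_pick = np.random.default_rng(0)
        for key in ("enc0/Ml", "enc1/tcn_w", "enc0/ca_W1", "enc1/ca_W2", "clf_W"):
            arr = m.params[key]
            flat_idx = rng_pick.integers(arr.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                eps = 1e-6
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_fn()
                arr[idx] = orig - eps
                lm = loss_fn()
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8), key


class TestAnnTwinAndAblation:
    def test_twin_parameter_parity(self, tiny_config):
        snn = MFSNN(tiny_config)
        ann = build_mfann(tiny_config)
        assert snn.n_parameters == ann.n_parameters
        assert {k: v.shape for k, v in snn.params.items()} == {
            k: v.shape for k, v in ann.params.items()
        }

    def test_ann_forward_deterministic(self, tiny_config, tiny_batch):
        ann = build_mfann(tiny_config)
        np.testing.assert_array_equal(ann.forward(tiny_batch), ann.forward(tiny_batch))

    def test_drop_ca_equals_weights_forced_to_one(self, tiny_config, tiny_batch):
        m_full = MFSNN(tiny_config)
        m_abl = MFSNN(ablate(tiny_config, "CA"))
        # share the non-CA parameters
        for k in m_abl.params:
            m_abl.params[k] = m_full.params[k].copy()
        logits_abl = m_abl.forward(tiny_batch)
        # force the full model's attention output to 1 by saturating biases
        for i in range(tiny_config.n_subencoders):
            m_full.params[f"enc{i}/ca_W1"][:] = 0.0
            m_full.params[f"enc{i}/ca_b1"][:] = 10.0
            m_full.params[f"enc{i}/ca_W2"][:] = 0.0
            m_full.params[f"enc{i}/ca_b2"][:] = 10.0
        np.testing.assert_allclose(m_full.forward(tiny_batch), logits_abl, atol=1e-12)

    def test_drop_tcn_output_independent_of_tcn_kernels(self, tiny_config, tiny_batch):
        m = MFSNN(ablate(tiny_config, "TCN"))
        assert not any("tcn" in k for k in m.params)
        base = m.forward(tiny_batch)
        np.testing.assert_array_equal(base, m.forward(tiny_batch))

    def test_drop_lt_uses_attention_scaled_tcn_only(self, tiny_config, tiny_batch):
        m = MFSNN(ablate(tiny_config, "LT"))
        assert not any("Ml" in k for k in m.params)
        assert m.forward(tiny_batch).shape == (6, 4)

    def test_unknown_ablation_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="unknown ablation"):
            ablate(tiny_config, "classifier")


class TestSubpathSymmetry:
    def test_permuting_subpaths_with_parameters_preserves_logits(self, tiny_config):
        """Swapping whole sub-encoder blocks together with their parameters
        and the matching classifier columns leaves the logits unchanged."""
        m = MFSNN(tiny_config)
        rng = np.random.default_rng(9)
        x = rng.poisson(1.0, (3, 16, 20)).astype(float)
        base = m.forward(x)

        cfg = m.config
        C, Tp = cfg.C, cfg.sub_encoder.T_prime
        # swap sub-encoders 0 and 1: input blocks, params, classifier columns
        x_sw = x.copy()
        x_sw[:, :C], x_sw[:, C : 2 * C] = x[:, C : 2 * C], x[:, :C].copy()
        m_sw = m.copy()
        for name in ("Ml", "tcn_w", "tcn_b", "ca_W1", "ca_b1", "ca_W2", "ca_b2"):
            m_sw.params[f"enc0/{name}"] = m.params[f"enc1/{name}"].copy()
            m_sw.params[f"enc1/{name}"] = m.params[f"enc0/{name}"].copy()
        W = m.params["clf_W"].reshape(cfg.n_classes, cfg.n_channels, Tp)
        W_sw = W.copy()
        W_sw[:, :C], W_sw[:, C : 2 * C] = W[:, C : 2 * C], W[:, :C].copy()
        m_sw.params["clf_W"] = W_sw.reshape(cfg.n_classes, -1)
        np.testing.assert_allclose(m_sw.forward(x_sw), base, atol=1e-12)


class TestCheckpoint:
    def test_bit_exact_round_trip(self, tiny_model, tiny_batch, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == tiny_model.config
        assert set(loaded.params) == set(tiny_model.params)
        for k in tiny_model.params:
            np.testing.assert_array_equal(loaded.params[k], tiny_model.params[k])
        np.testing.assert_array_equal(
            loaded.forward(tiny_batch), tiny_model.forward(tiny_batch)
        )
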