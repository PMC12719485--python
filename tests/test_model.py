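import numpy as np
import pytest

from ulcerstage.autodiff import Tensor
from ulcerstage.model import (AttentionHeadConfig, BackboneSpec, ClassifierHead,
                              ClassifierHeadConfig, EnhancedAttention,
                              StagingNetwork, StochasticDepthSchedule,
                              classifier_forward, count_parameters,
                              enhanced_attention, hierarchical_fuse,
                              load_checkpoint, save_checkpoint, tiny_spec)


class TestEnhancedAttentionFunction:
    def test_singleton_softmax_returns_value_row(self):
        q = np.array([[2.0]])
        k = np.array([[3.0]])
        v = np.array([[7.0]])
        out = enhanced_attention(q, k, v)
        assert np.allclose(out, 7.0)

    def test_hand_softmax_two_keys(self):
        """d_k = 1, scores [1, 0], V = (1, 0)^T -> e/(e+1) = 0.7310586."""
        q = np.array([[1.0]])
        k = np.array([[1.0], [0.0]])
        v = np.array([[1.0], [0.0]])
        out = enhanced_attention(q, k, v)
        assert out[0, 0] == pytest.approx(np.e / (np.e + 1), abs=1e-12)
        assert out[0, 0] == pytest.approx(0.7310585786300049, abs=1e-12)

    def test_large_negative_off_diagonal_bias_gives_identity(self, rng):
        x = rng.standard_normal((4, 6))
        r_pos = np.full((4, 4), -1e6)
        np.fill_diagonal(r_pos, 0.0)
        out = enhanced_attention(x, x, x, heads=1, r_pos=r_pos)
        assert np.allclose(out, x, atol=1e-8)

    def test_zero_bias_equals_naive_scaled_dot_product(self, rng):
        """Against an independent loop-and-normalize implementation."""
        q, k, v = (rng.standard_normal((5, 8)) for _ in range(3))
        heads = 2
        expected = np.zeros((5, 8))
        for h in range(heads):
            sl = slice(h * 4, (h + 1) * 4)
            for i in range(5):
                scores = np.array([q[i, sl] @ k[j, sl] for j in range(5)]) / 2.0
                w = np.exp(scores - scores.max())
                w /= w.sum()
                expected[i, sl] = sum(w[j] * v[j, sl] for j in range(5))
        assert np.allclose(enhanced_attention(q, k, v, heads=heads), expected, atol=1e-12)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            enhanced_attention(np.ones((2, 6)), np.ones((2, 6)), np.ones((2, 6)), heads=4)

    def test_attention_weight_rows_sum_to_one(self, rng):
        """With V = I the output rows are exactly the softmax weights."""
        q = rng.standard_normal((4, 4))
        k = rng.standard_normal((4, 4))
        out = enhanced_attention(q, k, np.eye(4), heads=1,
                                 r_pos=rng.standard_normal((4, 4)))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert (out >= 0).all()


class TestEnhancedAttentionModule:
    def test_module_matches_functional_form(self, rng):
        cfg = AttentionHeadConfig(heads=2, dim=8)
        mod = EnhancedAttention(cfg, np.random.default_rng(0))
        x = rng.standard_normal((1, 5, 8))
        out = mod(Tensor(x)).data
        q = x[0] @ mod.wq.weight.data + mod.wq.bias.data
        k = x[0] @ mod.wk.weight.data + mod.wk.bias.data
        v = x[0] @ mod.wv.weight.data + mod.wv.bias.data
        expected = (enhanced_attention(q, k, v, heads=2) @ mod.wo.weight.data
                    + mod.wo.bias.data)
        assert np.allclose(out[0], expected, atol=1e-10)

    def test_trainable_size_closed_form(self):
        """4 d (d+1): the Table-7 delta at d = 768, and 80 at d = 4."""
        toy = EnhancedAttention(AttentionHeadConfig(heads=2, dim=4),
                                np.random.default_rng(0))
        assert toy.n_parameters() == 4 * 4 * 5 == 80
        full = EnhancedAttention(AttentionHeadConfig(heads=8, dim=768),
                                 np.random.default_rng(0), init="empty")
        assert full.n_parameters() == 4 * 768 * 769 == 2_362_368


class TestHierarchicalFuse:
    def test_zero_projections_return_cls_vector(self, rng):
        taps = [rng.standard_normal((5, 8)) for _ in range(3)]
        cls_vec = rng.standard_normal(8)
        fused = hierarchical_fuse(taps, cls_vec, [np.zeros((8, 8))] * 3)
        assert np.allclose(fused, cls_vec)

    def test_tiny_hand_computation(self):
        tap = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])  # mean (3,4,5,6)
        w = np.zeros((4, 4))
        w[0, 1] = 1.0  # projection routes pooled[0] into slot 1
        cls_vec = np.array([10.0, 0.0, 0.0, 0.0])
        fused = hierarchical_fuse([tap], cls_vec, [w])
        assert np.allclose(fused, [10.0, 3.0, 0.0, 0.0])

    def test_mismatched_projections_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_fuse([rng.standard_normal((3, 4))], np.zeros(4), [])

    def test_full_scale_output_length(self, micro_net):
        spec = micro_net.spec
        x = np.random.default_rng(0).random((2, 3, spec.img_size, spec.img_size))
        logits = micro_net.forward(x)
        assert logits.shape == (2, 6)


class TestClassifierHead:
    def test_six_logits_and_eval_determinism(self, rng):
        head = ClassifierHead(ClassifierHeadConfig((8, 8, 4, 6), 0.3),
                              np.random.default_rng(0))
        feats = rng.standard_normal((3, 8))
        a = classifier_forward(feats, head, "eval")
        b = classifier_forward(feats, head, "eval")
        assert a.shape == (3, 6)
        assert np.array_equal(a, b)

    def test_train_mode_requires_rng_and_applies_dropout(self, rng):
        head = ClassifierHead(ClassifierHeadConfig((8, 8, 4, 6), 0.5),
                              np.random.default_rng(0))
        feats = rng.standard_normal((64, 8))
        with pytest.raises(ValueError):
            classifier_forward(feats, head, "train")
        a = classifier_forward(feats, head, "train", np.random.default_rng(1))
        b = classifier_forward(feats, head, "train", np.random.default_rng(2))
        assert not np.array_equal(a, b)

    def test_wrong_feature_length_rejected(self, rng):
        head = ClassifierHead(ClassifierHeadConfig((8, 8, 4, 6), 0.0),
                              np.random.default_rng(0))
        with pytest.raises(ValueError):
            classifier_forward(rng.standard_normal((2, 5)), head)

    def test_tiny_head_hand_computed(self):
        """W1 = I, chosen W2/W3, no dropout: the GELU/LayerNorm chain is
        hand-derivable because GELU(x) - GELU(-x) = x exactly."""
        head = ClassifierHead(ClassifierHeadConfig((4, 4, 2, 2), 0.0),
                              np.random.default_rng(0), init="zeros")
        head.fc1.weight.data = np.eye(4)
        head.fc2.weight.data = np.array([[1.0, 0.0], [0.0, 1.0],
                                         [1.0, 0.0], [0.0, 1.0]])
        head.fc3.weight.data = np.array([[1.0, 2.0], [3.0, 4.0]])
        x = np.array([[1.0, -1.0, 1.0, -1.0]])
        # GELU -> (0.84134, -0.15866, ...), LN -> (1, -1, 1, -1)
        # W2 -> (2, -2), GELU -> (1.95450, -0.04550), LN -> (1, -1)
        # W3 -> (1*1 - 1*3, 1*2 - 1*4) = (-2, -2)
        out = classifier_forward(x, head, "eval")
        assert out[0] == pytest.approx([-2.0, -2.0], abs=1e-4)

    def test_gelu_of_zero_is_zero(self):
        head = ClassifierHead(ClassifierHeadConfig((4, 4, 2, 2), 0.0),
                              np.random.default_rng(0), init="zeros")
        out = classifier_forward(np.zeros((1, 4)), head, "eval")
        assert np.allclose(out, 0.0)

    def test_kaiming_preactivation_variance_band(self):
        """He-normal fan-in init keeps layer-1 pre-activation variance near
        the design gain of 2 on unit-variance input (sanity band, 10^3 trials)."""
        rng = np.random.default_rng(0)
        head = ClassifierHead(ClassifierHeadConfig((256, 256, 128, 6), 0.0), rng)
        x = rng.standard_normal((1000, 256))
        pre = x @ head.fc1.weight.data + head.fc1.bias.data
        assert 0.5 < pre.var() / 2.0 < 2.0


class TestParameterCounts:
    def test_full_scale_variants(self):
        standard = count_parameters("standard")
        enhanced = count_parameters("enhanced")
        assert standard == 86_654_022
        assert enhanced == 89_016_390
        assert enhanced - standard == 4 * 768 * 769

    def test_count_invariant_to_seed_and_weights(self):
        spec = tiny_spec()
        a = StagingNetwork(spec, seed=0).n_parameters()
        b = StagingNetwork(spec, seed=99).n_parameters()
        assert a == b

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            count_parameters("extreme")


class TestStochasticDepth:
    def test_schedule_linear_and_nondecreasing(self):
        rates = StochasticDepthSchedule(12, 0.1).rates()
        assert rates[0] == 0.0
        assert rates[-1] == pytest.approx(0.1)
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_rate_zero_training_forward_is_deterministic(self):
        spec = tiny_spec(img_size=16, depth=2, dim=8, heads=2, patch_size=8)
        net = StagingNetwork(spec, seed=0, attention_heads=2,
                             head_dropout=0.0, stochastic_depth=0.0)
        x = np.random.default_rng(0).random((2, 3, 16, 16))
        a = net.forward(x, train=True, rng=np.random.default_rng(1)).data
        b = net.forward(x, train=False).data
        assert np.allclose(a, b)

    def test_nonzero_rate_perturbs_training_forward(self):
        spec = tiny_spec(img_size=16, depth=2, dim=8, heads=2, patch_size=8)
        net = StagingNetwork(spec, seed=0, attention_heads=2,
                             head_dropout=0.0, stochastic_depth=0.9)
        x = np.random.default_rng(0).random((2, 3, 16, 16))
        outs = {net.forward(x, train=True, rng=np.random.default_rng(s)).data.tobytes()
                for s in range(6)}
        assert len(outs) > 1


class TestCheckpointIO:
    def test_roundtrip_preserves_weights_and_meta(self, tmp_path, micro_net):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, micro_net, epoch=5, fold=2)
        other = StagingNetwork(micro_net.spec, seed=123, attention_heads=2,
                               head_dropout=0.0, stochastic_depth=0.0)
        x = np.random.default_rng(0).random((1, 3, 16, 16))
        assert not np.allclose(other.forward(x).data, micro_net.forward(x).data)
        meta = load_checkpoint(path, other)
        assert meta["epoch"] == 5 and meta["fold"] == 2
        assert np.allclose(other.forward(x).data, micro_net.forward(x).data)


class TestBackboneSpec:
    def test_tap_blocks_must_lie_in_depth(self):
        with pytest.raises(ValueError):
            BackboneSpec(depth=4, dim=32, heads=4, tap_blocks=(2, 9))

    def test_dim_head_divisibility(self):
        with pytest.raises(ValueError):
            BackboneSpec(depth=2, dim=30, heads=4, tap_blocks=(1,))

    def test_missing_tap_is_architecture_error(self):
        spec = tiny_spec(img_size=16, depth=2, dim=8, heads=2, patch_size=8)
        net = StagingNetwork(spec, seed=0, attention_heads=2)
        net.blocks = net.blocks[:1]  # break the encoder: block 2 never runs
        with pytest.raises(RuntimeError, match="tap"):
            net.forward(np.zeros((1, 3, 16, 16)))
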