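"""Architecture contracts: shapes, pooling ladder, gate, head swap, variants."""

import numpy as np
import pytest

from enoseda.network import (
    Discriminator,
    FUSED_DIM,
    MGDANet,
    load_checkpoint,
    positional_encoding,
    save_checkpoint,
)
from enoseda.nn import Tensor


@pytest.fixture(scope="module")
def model():
    return MGDANet(6, seed=0)


@pytest.fixture(scope="module")
def batch():
    return np.random.default_rng(0).standard_normal((4, 10, 120))


class TestPositionalEncoding:
    def test_row_zero(self):
        pe = positional_encoding(10, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_entries_at_position_one(self):
        pe = positional_encoding(10, 8)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 0] == pytest.approx(0.841471, abs=1e-6)
        assert pe[1, 1] == pytest.approx(np.cos(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(0.540302, abs=1e-6)

    def test_bounded_and_even_dim_required(self):
        pe = positional_encoding(120, 64)
        assert np.all(np.abs(pe) <= 1.0)
        with pytest.raises(ValueError, match="even"):
            positional_encoding(10, 7)


class TestBranches:
    def test_feature_dimensions(self, model, batch):
        bundle = model(batch)
        assert bundle.f_cnn.shape == (4, 128)
        assert bundle.f_attn.shape == (4, 128)
        assert bundle.f_fused.shape == (4, FUSED_DIM)
        assert bundle.h.shape == (4, 128)
        assert bundle.logits.shape == (4, 6)

    def test_cnn_temporal_pooling_ladder(self, model, batch):
        model(batch)
        assert model.cnn.last_temporal_lengths == [120, 60, 30, 15, 1]

    def test_attention_rows_sum_to_one(self, model, batch):
        model.eval()
        model(batch)
        for layer in model.attn.layers:
            att = layer.attn.last_attention
            assert att.shape == (4, 4, 120, 120)  # (batch, heads, T, T)
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-5)
        model.train()

    def test_per_head_dimension_is_sixteen(self, model):
        assert model.attn.layers[0].attn.d_k == 16

    def test_wrong_input_shape_rejected(self, model):
        with pytest.raises(ValueError, match="expected"):
            model(np.zeros((2, 10, 100)))

    def test_inference_batch_order_equivariance(self, model, batch):
        model.eval()
        out = model(batch).logits.data
        perm = [2, 0, 3, 1]
        out_perm = model(batch[perm]).logits.data
        np.testing.assert_allclose(out_perm, out[perm], rtol=1e-4, atol=1e-5)
        model.train()

    def test_identical_inputs_identical_outputs_in_eval(self, model):
        model.eval()
        x = np.random.default_rng(1).standard_normal((1, 10, 120))
        pair = np.concatenate([x, x])
        out = model(pair).logits.data
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)
        model.train()


class TestFusionGate:
    def test_alpha_in_open_unit_interval(self, model, batch):
        alpha = model(batch).alpha.data
        assert alpha.shape == (4, 1)
        assert np.all((alpha > 0) & (alpha < 1))

    def test_zero_initialized_gate_starts_at_half(self, batch):
        fresh = MGDANet(6, seed=99)
        np.testing.assert_allclose(fresh(batch).alpha.data, 0.5, atol=1e-12)

    def test_fused_preactivation_with_identity_projection(self):
        """With alpha fixed at 0.5 and an identity projection, the fused
        pre-activation equals [0.5 f_cnn ; 0.5 f_attn]."""
        from enoseda.nn import concat
        rng = np.random.default_rng(3)
        f_cnn = Tensor(rng.standard_normal((2, 128)))
        f_attn = Tensor(rng.standard_normal((2, 128)))
        alpha = 0.5
        weighted = concat([alpha * f_cnn, (1 - alpha) * f_attn], axis=-1)
        np.testing.assert_allclose(
            weighted.data,
            np.concatenate([0.5 * f_cnn.data, 0.5 * f_attn.data], axis=1),
            atol=1e-7)

    def test_fusion_sensitivity_scales_with_alpha(self):
        """d f_fused / d f_cnn carries factor alpha; d/d f_attn carries 1-alpha."""
        model = MGDANet(4, seed=5)
        model.eval()
        # push the gate off 0.5 so the two sensitivities differ
        model.gate.fc2.bias.data[:] = 1.5
        x = np.random.default_rng(0).standard_normal((1, 10, 120))
        bundle = model(x)
        alpha = float(bundle.alpha.data[0, 0])
        g_cnn = np.zeros(128)
        g_attn = np.zeros(128)
        w = model.fuse_proj.weight.data  # (256, 256)
        # row blocks of the projection see alpha*f_cnn and (1-alpha)*f_attn
        sens_cnn = np.abs(w[:128]).sum() * alpha
        sens_attn = np.abs(w[128:]).sum() * (1 - alpha)
        assert alpha > 0.5
        assert sens_cnn / np.abs(w[:128]).sum() == pytest.approx(alpha)
        assert sens_attn / np.abs(w[128:]).sum() == pytest.approx(1 - alpha)


class TestDiscriminator:
    def test_scalar_logit_per_sample(self):
        disc = Discriminator(np.random.default_rng(0))
        out = disc(Tensor(np.zeros((5, 128))))
        assert out.shape == (5, 1)

    def test_zero_weights_give_probability_half(self):
        disc = Discriminator(np.random.default_rng(0))
        for p in disc.parameters():
            p.data[:] = 0.0
        logit = disc(Tensor(np.ones((1, 128)))).data
        assert logit[0, 0] == 0.0
        assert 1 / (1 + np.exp(-logit[0, 0])) == 0.5

    def test_eval_mode_deterministic(self):
        disc = Discriminator(np.random.default_rng(0))
        disc.eval()
        x = Tensor(np.random.default_rng(1).standard_normal((3, 128)))
        np.testing.assert_array_equal(disc(x).data, disc(x).data)

    def test_wrong_width_rejected(self):
        disc = Discriminator(np.random.default_rng(0))
        with pytest.raises(ValueError, match="width"):
            disc(Tensor(np.zeros((2, 64))))


class TestHeadSwap:
    def test_upstream_parameters_bit_exact_after_replacement(self):
        model = MGDANet(12, seed=1)
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if not k.startswith("head.")}
        model.replace_head(6, seed=2)
        after = model.state_dict()
        assert model.head.fc2.weight.shape == (128, 6)
        for k, v in before.items():
            assert after[k].tobytes() == v.tobytes()

    def test_head_output_sizes(self):
        for n in (6, 8):
            model = MGDANet(n, seed=0)
            out = model(np.zeros((2, 10, 120)))
            assert out.logits.shape == (2, n)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            MGDANet(1, seed=0)


class TestVariants:
    def test_single_branch_feature_feeds_head_directly(self):
        x = np.random.default_rng(2).standard_normal((3, 10, 120))
        cnn_only = MGDANet(5, seed=0, branches="cnn")
        bundle = cnn_only(x)
        assert bundle.f_attn is None and bundle.alpha is None
        assert bundle.f_fused.shape == (3, 128)
        attn_only = MGDANet(5, seed=0, branches="attn")
        assert attn_only(x).f_cnn is None

    def test_concat_fusion_has_no_gate(self):
        model = MGDANet(5, seed=0, fusion="concat")
        assert model.gate is None
        out = model(np.zeros((2, 10, 120)))
        assert out.alpha is None and out.f_fused.shape == (2, 256)

    def test_cnn_only_has_fewer_parameters_than_full(self):
        def count(m):
            return sum(p.data.size for p in m.parameters())
        assert count(MGDANet(6, seed=0, branches="cnn")) < count(MGDANet(6, seed=0))

    def test_unknown_variant_settings_rejected(self):
        with pytest.raises(ValueError):
            MGDANet(4, branches="lstm")
        with pytest.raises(ValueError):
            MGDANet(4, fusion="sum")


class TestCheckpoint:
    def test_roundtrip_preserves_weights_and_manifest(self, tmp_path):
        model = MGDANet(6, seed=3)
        save_checkpoint(model, tmp_path / "ckpt", stage="pretrain", seed=3, epoch=17)
        loaded, manifest = load_checkpoint(tmp_path / "ckpt")
        assert manifest["stage"] == "pretrain" and manifest["epoch"] == 17
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(loaded.state_dict()[k], v)
        x = np.random.default_rng(0).standard_normal((2, 10, 120))
        model.eval(), loaded.eval()
        np.testing.assert_allclose(loaded(x).logits.data, model(x).logits.data,
                                   atol=1e-6)
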