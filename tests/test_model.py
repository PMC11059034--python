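import dataclasses

import numpy as np
import pytest

from uswinct.autodiff import Tensor
from uswinct.model import (
    ModelConfig,
    PRESETS,
    SwinLayer,
    UNetBranch,
    USTBlock,
    USwin,
    WindowAttention,
    _shift_attention_mask,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    window_partition,
    window_reverse,
)


def tiny_cfg(**kw):
    base = dict(
        hidden_channels=8,
        n_ust_modules=1,
        st_blocks_per_ust=2,
        n_heads=2,
        window_size=4,
        unet_depth=2,
        rng_seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestWindowPartition:
    def test_8x8_m4_gives_4_windows_of_16_tokens(self, rng):
        x = rng.normal(size=(8, 8, 3))
        w = window_partition(x, 4)
        assert w.shape == (4, 16, 3)

    def test_reverse_is_exact_inverse(self, rng):
        x = rng.normal(size=(16, 16, 5))
        np.testing.assert_array_equal(window_reverse(window_partition(x, 8), 8, 16, 16), x)

    def test_tokens_are_a_permutation(self, rng):
        x = rng.normal(size=(16, 16, 1))
        w = window_partition(x, 8)
        assert w.shape[0] == 4
        assert sorted(w.ravel().tolist()) == sorted(x.ravel().tolist())

    def test_indivisible_input_is_padded(self, rng):
        x = rng.normal(size=(10, 14, 2))
        w = window_partition(x, 8)
        assert w.shape == (4, 64, 2)  # padded up to 16x16
        np.testing.assert_array_equal(window_reverse(w, 8, 10, 14), x)


def dense_attention_oracle(x, wa: WindowAttention):
    """Independent dense softmax attention using the layer's own weights."""
    h, d = wa.n_heads, wa.head_dim
    q = x @ wa.q.weight.data + wa.q.bias.data
    k = x @ wa.k.weight.data + wa.k.bias.data
    v = x @ wa.v.weight.data + wa.v.bias.data
    bias = wa.bias_table.data[wa._rel_index]  # T, T, h
    outs = []
    T = x.shape[0]
    for head in range(h):
        qh, kh, vh = (m[:, head * d : (head + 1) * d] for m in (q, k, v))
        logits = qh @ kh.T / np.sqrt(d) + bias[:, :, head]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        outs.append(attn @ vh)
    return np.concatenate(outs, axis=1) @ wa.proj.weight.data + wa.proj.bias.data


class TestWindowAttention:
    def test_matches_dense_oracle_on_random_window(self, rng):
        wa = WindowAttention(c=6, n_heads=2, M=2, rng=np.random.default_rng(0))
        x = rng.normal(size=(1, 4, 6))  # one 2x2 window, 4 tokens
        out = wa(Tensor(x)).data[0]
        expected = dense_attention_oracle(x[0], wa)
        np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-9)

    def test_single_token_window_passes_value_through(self):
        wa = WindowAttention(c=3, n_heads=1, M=1, rng=np.random.default_rng(0))
        # identity value/output projections, zero bias: softmax over one
        # element is 1, so the output is the token's value row
        wa.v.weight.data = np.eye(3)
        wa.proj.weight.data = np.eye(3)
        wa.bias_table.data[:] = 0.0
        x = np.array([[[0.3, -1.2, 2.0]]])
        np.testing.assert_allclose(wa(Tensor(x)).data, x, atol=1e-12)

    def test_zero_query_gives_uniform_mixing(self, rng):
        wa = WindowAttention(c=4, n_heads=2, M=2, rng=np.random.default_rng(1))
        wa.q.weight.data[:] = 0.0
        wa.q.bias.data[:] = 0.0
        wa.bias_table.data[:] = 0.0
        wa.v.weight.data = np.eye(4)
        wa.v.bias.data[:] = 0.0
        wa.proj.weight.data = np.eye(4)
        wa.proj.bias.data[:] = 0.0
        x = rng.normal(size=(1, 4, 4))
        out = wa(Tensor(x)).data[0]
        np.testing.assert_allclose(out, np.tile(x[0].mean(axis=0), (4, 1)), atol=1e-12)

    def test_global_window_equals_dense_attention(self, rng):
        # one window covering the whole (padded) map is plain dense attention
        wa = WindowAttention(c=4, n_heads=2, M=4, rng=np.random.default_rng(2))
        x = rng.normal(size=(1, 16, 4))
        np.testing.assert_allclose(
            wa(Tensor(x)).data[0], dense_attention_oracle(x[0], wa), rtol=1e-6, atol=1e-9
        )

    def test_relative_bias_depends_only_on_offset(self):
        wa = WindowAttention(c=4, n_heads=1, M=4, rng=np.random.default_rng(0))
        idx = wa._rel_index
        M = 4
        # tokens (0,0)->(1,1) and (1,1)->(2,2) share the relative offset (1,1)
        assert idx[0, M + 1] == idx[M + 1, 2 * M + 2]


class TestSwinLayer:
    def test_zero_init_residual_paths_make_identity(self, rng):
        layer = SwinLayer(tiny_cfg(zero_init_residual_paths=True), shifted=False,
                          rng=np.random.default_rng(0))
        x = rng.normal(size=(1, 8, 8, 8))
        out = layer(Tensor(x.transpose(0, 3, 1, 2)))
        np.testing.assert_allclose(out.data, x.transpose(0, 3, 1, 2), atol=1e-12)

    @pytest.mark.parametrize("shifted", [False, True])
    def test_shape_preserved(self, shifted, rng):
        layer = SwinLayer(tiny_cfg(), shifted=shifted, rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 8, 12)))
        assert layer(x).shape == x.shape

    def test_shifted_equals_unshifted_on_constant_input(self):
        cfg = tiny_cfg()
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        plain = SwinLayer(cfg, shifted=False, rng=r1)
        shifted = SwinLayer(cfg, shifted=True, rng=r2)  # identical weights
        x = Tensor(np.full((1, 8, 8, 8), 0.7))
        np.testing.assert_allclose(plain(x).data, shifted(x).data, atol=1e-10)

    def test_shift_mask_blocks_exactly_cross_region_pairs(self):
        mask = _shift_attention_mask(8, 8, 4)
        assert mask.shape == (4, 16, 16)
        assert np.all((mask == 0) | (mask == -1e9))
        # the window at the wrapped corner mixes four regions: blocked pairs exist
        assert (mask[-1] == -1e9).any()
        # the interior window spans one region: nothing blocked
        assert (mask[0] == 0).all()


class TestUNetBranch:
    def test_shape_preserved(self, rng):
        u = UNetBranch(tiny_cfg(), rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 16, 16)))
        assert u(x).shape == x.shape

    def test_zero_final_conv_gives_zero_output(self, rng):
        u = UNetBranch(tiny_cfg(zero_init_residual_paths=True), rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 8, 8)))
        np.testing.assert_allclose(u(x).data, 0.0, atol=1e-12)

    def test_parameter_count_increases_with_depth(self):
        shallow = UNetBranch(tiny_cfg(unet_depth=2), rng=np.random.default_rng(0))
        deep = UNetBranch(tiny_cfg(unet_depth=3), rng=np.random.default_rng(0))
        assert deep.n_parameters() > shallow.n_parameters()

    def test_too_small_input_raises(self, rng):
        u = UNetBranch(tiny_cfg(unet_depth=3), rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="too small"):
            u(Tensor(rng.normal(size=(1, 8, 4, 4))))


class TestUSTBlock:
    def test_zero_init_fusion_is_identity(self, rng):
        block = USTBlock(tiny_cfg(zero_init_residual_paths=True), rng=np.random.default_rng(0))
        x = rng.normal(size=(1, 8, 8, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_shape_preserved(self, rng):
        block = USTBlock(tiny_cfg(), rng=np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8, 16, 16)))
        assert block(x).shape == x.shape

    def test_disabling_either_branch_reduces_parameters(self):
        full = USTBlock(tiny_cfg(), rng=np.random.default_rng(0)).n_parameters()
        no_unet = USTBlock(
            tiny_cfg(use_unet_branch=False), rng=np.random.default_rng(0)
        ).n_parameters()
        no_st = USTBlock(
            tiny_cfg(use_transformer_branch=False), rng=np.random.default_rng(0)
        ).n_parameters()
        assert no_unet < full and no_st < full

    def test_both_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            tiny_cfg(use_unet_branch=False, use_transformer_branch=False)


class TestUSwin:
    @pytest.mark.parametrize("hw", [(64, 64), (96, 96), (50, 70)])
    def test_output_shape_matches_input(self, hw, rng):
        model = USwin(tiny_cfg())
        x = rng.random(hw)
        assert model.predict(x).shape == hw

    def test_same_seed_same_outputs(self, rng):
        x = rng.random((16, 16))
        a = USwin(tiny_cfg(rng_seed=11)).predict(x)
        b = USwin(tiny_cfg(rng_seed=11)).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_preset_parameter_ordering(self):
        assert (
            count_parameters(PRESETS["uswin1"])
            < count_parameters(PRESETS["small"])
            < count_parameters(PRESETS["large"])
        )

    def test_every_ablation_flag_reduces_parameters(self):
        full = PRESETS["large"]
        n_full = count_parameters(full)
        for flag in ("use_long_skip", "use_unet_branch", "use_transformer_branch"):
            ablated = dataclasses.replace(full, **{flag: False})
            assert count_parameters(ablated) < n_full, flag

    def test_count_is_deterministic(self):
        cfg = tiny_cfg()
        assert count_parameters(cfg) == count_parameters(cfg)

    def test_gradient_reaches_every_parameter(self, rng):
        model = USwin(tiny_cfg())
        out = model.forward(rng.random((16, 16)))
        (out * out).sum().backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0.0)

    def test_long_skip_changes_output(self, rng):
        x = rng.random((16, 16))
        with_skip = USwin(tiny_cfg(rng_seed=4)).predict(x)
        without = USwin(tiny_cfg(rng_seed=4, use_long_skip=False)).predict(x)
        assert not np.allclose(with_skip, without)

    def test_checkpoint_roundtrip_bitexact(self, tmp_path, rng):
        model = USwin(tiny_cfg(rng_seed=9))
        x = rng.random((16, 16))
        before = model.predict(x)
        save_checkpoint(tmp_path / "m.npz", model)
        restored = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(before, restored.predict(x))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tiny_cfg(window_size=5)
        with pytest.raises(ValueError):
            tiny_cfg(hidden_channels=10, n_heads=4)
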