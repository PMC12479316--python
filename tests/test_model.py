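"""Architecture contracts: patch embedding, attention, blocks, encoder/decoder,
PatchGAN discriminator and the U-Net baseline."""

import numpy as np
import pytest

from attnfnet.model import (AttnFnetGenerator, DiscriminatorSpec,
                            GeneratorSpec, MultiHeadSelfAttention,
                            PatchGANDiscriminator, TransformerBlock,
                            build_discriminator, build_unet_baseline,
                            sinusoidal_positions)
from attnfnet.nn import Tensor

TINY = GeneratorSpec(input_shape=(64, 56), patch_size=8, embed_dim=64,
                     n_blocks=6, n_heads=4, skip_block_indices=(3, 4, 5),
                     decoder_channels=(64, 32, 16))


@pytest.fixture(scope="module")
def tiny_gen():
    return AttnFnetGenerator(TINY, seed=3)


def attention_loop_oracle(x, wq, bq, wk, bk, wv, bv, wo, bo, n_heads):
    """Three-nested-loop multi-head attention (no vectorization)."""
    n, d = x.shape
    dk = d // n_heads
    q, k, v = x @ wq + bq, x @ wk + bk, x @ wv + bv
    merged = np.zeros((n, d))
    for h in range(n_heads):
        sl = slice(h * dk, (h + 1) * dk)
        for i in range(n):
            logits = np.array([q[i, sl] @ k[j, sl] / np.sqrt(dk)
                               for j in range(n)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            for j in range(n):
                merged[i, sl] += w[j] * v[j, sl]
    return x + merged @ wo + bo


class TestPatchEmbedAndPositions:
    def test_patch_grid_arithmetic(self, tiny_gen):
        assert TINY.grid_shape == (8, 7)
        assert TINY.n_tokens == 56
        assert GeneratorSpec().grid_shape == (16, 7)

    def test_zero_image_zero_bias_gives_zero_tokens(self, tiny_gen):
        tokens = tiny_gen.patch_embed(np.zeros((64, 56)))
        assert tokens.shape == (56, 64)
        np.testing.assert_allclose(tokens.data, 0.0, atol=1e-15)

    def test_patch_locality(self, tiny_gen):
        rng = np.random.default_rng(0)
        a = rng.random((64, 56))
        b = a.copy()
        b[8:16, 8:16] += 1.0   # exactly patch (row 1, col 1) -> token 8
        ta = tiny_gen.patch_embed(a).data
        tb = tiny_gen.patch_embed(b).data
        changed = np.where(np.abs(ta - tb).max(axis=1) > 1e-12)[0]
        assert list(changed) == [1 * 7 + 1]

    def test_indivisible_shape_rejected(self, tiny_gen):
        with pytest.raises(ValueError, match="does not match"):
            tiny_gen.patch_embed(np.zeros((63, 56)))
        with pytest.raises(ValueError, match="divisible"):
            GeneratorSpec(input_shape=(60, 56), patch_size=8)

    def test_sinusoidal_position_zero_row(self):
        pe = sinusoidal_positions((4, 4), 16)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_sinusoidal_bounded_and_distinct(self):
        pe = sinusoidal_positions((16, 7), 32)
        assert np.abs(pe).max() <= 1.0
        assert len(np.unique(pe.round(9), axis=0)) == pe.shape[0]

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sinusoidal_positions((2, 2), 7)


class TestAttention:
    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        attn = MultiHeadSelfAttention(8, 2, rng)
        x = rng.standard_normal((6, 8))
        got = attn(Tensor(x)).data
        want = attention_loop_oracle(
            x, attn.wq.w.data, attn.wq.b.data, attn.wk.w.data, attn.wk.b.data,
            attn.wv.w.data, attn.wv.b.data, attn.wo.w.data, attn.wo.b.data, 2)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_single_token_degenerate_softmax(self):
        rng = np.random.default_rng(6)
        attn = MultiHeadSelfAttention(8, 2, rng)
        x = rng.standard_normal((1, 8))
        v = x @ attn.wv.w.data + attn.wv.b.data
        want = x + v @ attn.wo.w.data + attn.wo.b.data
        np.testing.assert_allclose(attn(Tensor(x)).data, want, atol=1e-12)

    def test_identical_values_make_queries_irrelevant(self):
        rng = np.random.default_rng(7)
        attn = MultiHeadSelfAttention(8, 2, rng)
        attn.wv.w.data = np.zeros((8, 8))       # V rows all equal bias
        x = rng.standard_normal((5, 8))
        core = attn.core(Tensor(x)).data
        want = attn.wv.b.data @ attn.wo.w.data + attn.wo.b.data
        np.testing.assert_allclose(core, np.tile(want, (5, 1)), atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        attn = MultiHeadSelfAttention(8, 4, rng)
        w = attn.attention_weights(Tensor(rng.standard_normal((9, 8))))
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)

    def test_nan_input_rejected(self):
        attn = MultiHeadSelfAttention(8, 2, np.random.default_rng(0))
        bad = np.full((3, 8), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            attn(Tensor(bad))


class TestTransformerBlock:
    @pytest.mark.parametrize("variant", ["conv", "mlp"])
    def test_shape_preserved(self, variant):
        rng = np.random.default_rng(1)
        blk = TransformerBlock(16, 4, (4, 3), variant, rng)
        x = Tensor(rng.standard_normal((12, 16)))
        assert blk(x).shape == (12, 16)

    @pytest.mark.parametrize("variant", ["conv", "mlp"])
    def test_zero_feedforward_reduces_to_attention_residual(self, variant):
        rng = np.random.default_rng(2)
        blk = TransformerBlock(16, 4, (4, 3), variant, rng)
        for p in blk.ff.parameters():
            p.data = np.zeros_like(p.data)
        x = Tensor(np.random.default_rng(3).standard_normal((12, 16)))
        attn_only = (x + blk.attn.core(blk.ln1(x))).data
        np.testing.assert_allclose(blk(x).data, attn_only, atol=1e-12)

    def test_conv_ff_receptive_field_is_local(self):
        """With attention silenced, the conv feed-forward spreads a token
        perturbation only within the 5x5 grid neighborhood of two 3x3 convs."""
        rng = np.random.default_rng(4)
        blk = TransformerBlock(8, 2, (6, 6), "conv", rng)
        # silence attention so only the FF path differs
        for lin in (blk.attn.wv, blk.attn.wo):
            lin.w.data = np.zeros_like(lin.w.data)
            lin.b.data = np.zeros_like(lin.b.data)
        base = np.random.default_rng(5).standard_normal((36, 8))
        pert = base.copy()
        pert[14] += 10.0                       # grid position (2, 2)
        diff = np.abs(blk(Tensor(pert)).data - blk(Tensor(base)).data).max(axis=1)
        affected = set(np.where(diff > 1e-9)[0])
        r, c = 2, 2
        allowed = {i * 6 + j for i in range(6) for j in range(6)
                   if abs(i - r) <= 2 and abs(j - c) <= 2}
        assert affected <= allowed
        assert 14 in affected

    def test_token_count_mismatch_rejected(self):
        blk = TransformerBlock(8, 2, (4, 3), "conv", np.random.default_rng(0))
        with pytest.raises(ValueError, match="inconsistent"):
            blk(Tensor(np.zeros((10, 8))))


class TestEncodeDecode:
    def test_skips_have_expected_keys_and_shapes(self, tiny_gen):
        latent, skips = tiny_gen.encode(np.random.default_rng(0).random((64, 56)))
        assert set(skips) == {3, 4, 5}
        assert latent.shape == (56, 64)
        for t in skips.values():
            assert t.shape == (56, 64)

    def test_block_weights_after_skips_do_not_affect_skips(self, tiny_gen):
        x = np.random.default_rng(1).random((64, 56))
        latent_a, skips_a = tiny_gen.encode(x)
        p = tiny_gen.blocks[5].attn.wq.w   # block 6, after all skip taps
        old = p.data.copy()
        p.data = p.data + np.random.default_rng(0).normal(0, 0.5, p.data.shape)
        latent_b, skips_b = tiny_gen.encode(x)
        p.data = old
        assert np.abs(latent_a.data - latent_b.data).max() > 1e-9
        for k in skips_a:
            np.testing.assert_array_equal(skips_a[k].data, skips_b[k].data)

    def test_output_shape_and_range(self, tiny_gen):
        out = tiny_gen(np.random.default_rng(2).random((64, 56)))
        assert out.shape == (27, 64)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_zeroing_a_skip_changes_output(self, tiny_gen):
        x = np.random.default_rng(3).random((64, 56))
        latent, skips = tiny_gen.encode(x)
        base = tiny_gen.decode(latent, skips).data
        skips[5] = Tensor(np.zeros_like(skips[5].data))
        ablated = tiny_gen.decode(latent, skips).data
        assert np.abs(base - ablated).max() > 1e-9

    def test_missing_skip_rejected(self, tiny_gen):
        latent, skips = tiny_gen.encode(np.zeros((64, 56)) + 0.5)
        del skips[4]
        with pytest.raises(ValueError, match="expected skips"):
            tiny_gen.decode(latent, skips)

    def test_gradient_reaches_first_block(self, tiny_gen):
        tiny_gen.zero_grad()
        out = tiny_gen(np.random.default_rng(4).random((64, 56)))
        ((out - 0.5) ** 2.0).mean().backward()
        grads = [p.grad for p in tiny_gen.blocks[0].parameters()]
        assert all(g is not None for g in grads)
        assert max(np.abs(g).max() for g in grads) > 0
        tiny_gen.zero_grad()

    def test_ff_variants_are_shape_interchangeable(self):
        rng = np.random.default_rng(0)
        x = rng.random((64, 56))
        outs = {}
        for variant in ("conv", "mlp"):
            spec = GeneratorSpec(**{**TINY.to_dict(), "ff_variant": variant})
            G = AttnFnetGenerator(spec, seed=1)
            latent, skips = G.encode(x)
            assert latent.shape == (56, 64)
            outs[variant] = G(x).shape
        assert outs["conv"] == outs["mlp"] == (27, 64)

    def test_same_seed_identical_initialization(self):
        a = AttnFnetGenerator(TINY, seed=9)
        b = AttnFnetGenerator(TINY, seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestDiscriminator:
    def test_logit_map_is_2d_grid(self):
        D = build_discriminator(seed=0)
        out = D(np.random.default_rng(0).random((64, 56)),
                np.random.default_rng(1).random((27, 64)))
        assert out.ndim == 4 and out.shape[2] >= 1 and out.shape[3] >= 1

    def test_scalar_probability_in_unit_interval(self):
        D = build_discriminator(seed=0)
        p = D.scalar_probability(np.random.default_rng(2).random((64, 56)),
                                 np.random.default_rng(3).random((27, 64)))
        assert 0.0 < p.item() < 1.0

    def test_receptive_field_probe_matches_analytic(self):
        spec = DiscriminatorSpec()
        D = PatchGANDiscriminator(spec, seed=0)
        depth = np.full((64, 56), 0.5)
        base_p = np.full((27, 64), 0.5)
        base = D(depth, base_p).data[0, 0]
        # probe: perturb each pressure pixel, record which logits move
        rf = spec.receptive_field
        moved_cols = set()
        target = (base.shape[0] // 2, base.shape[1] // 2)
        for j in range(64):
            p = base_p.copy()
            p[13, j] += 1.0
            out = D(depth, p).data[0, 0]
            if abs(out[target] - base[target]) > 1e-12:
                moved_cols.add(j)
        # the probe column span equals the analytic receptive field clipped
        # to the image; center logit of a 64-wide map sees at most rf columns
        lo = min(moved_cols)
        hi = max(moved_cols)
        assert hi - lo + 1 <= rf
        assert hi - lo + 1 >= rf - spec.kernel  # within one stride step

    def test_unaligned_pressure_rejected(self):
        D = build_discriminator(seed=0)
        with pytest.raises(ValueError, match="does not match"):
            D(np.zeros((64, 56)), np.zeros((64, 27)))


class TestUNetBaseline:
    def test_contract_and_param_count(self):
        U = build_unet_baseline(input_shape=(64, 56))
        out = U(np.random.default_rng(0).random((64, 56)))
        assert out.shape == (27, 64)
        assert 0.0 <= out.data.min() and out.data.max() <= 1.0
        assert U.n_parameters() > 0

    def test_seeded_init_reproducible(self):
        a = build_unet_baseline(input_shape=(64, 56), seed=4)
        b = build_unet_baseline(input_shape=(64, 56), seed=4)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
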